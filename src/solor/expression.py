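"""Expression-level summaries from sectioned cell counts.

Counts of labelled olfactory sensory neurons are taken on a subsample of
coronal sections (every eighth 12-um section by default) and corrected for
the over-counting of cells split across section faces with Abercrombie's
method, N = n * T / (T + h), where T is section thickness and h the mean
particle (nucleus) height.  Per-gene totals over animals are summarised as
mean, sample standard deviation and coefficient of variation (CV = sd /
mean), and the relation between expression magnitude and its dispersion is
tested with a Pearson correlation (two-sided p from the t distribution on
n - 2 degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SectionCounts",
    "CountEstimate",
    "CorrelationResult",
    "abercrombie_correct",
    "estimate_total",
    "summarize_counts",
    "estimate_from_mean_sd",
    "pearson_with_p",
    "load_reference_cell_counts",
    "mean_cv_correlation",
]


@dataclass
class SectionCounts:
    """Raw per-section neuron counts for one gene in one animal.

    ``section_thickness_um`` defaults to 12 (cryostat sections); the
    particle height ``particle_height_um`` has no default because it is a
    property of the measured nuclei, not of the protocol.
    ``sampling_interval`` is the section stride (8 = every eighth section).
    """

    gene_id: str
    animal_id: str
    counts: list[int]
    section_thickness_um: float = 12.0
    particle_height_um: float = 0.0
    sampling_interval: int = 8

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.section_thickness_um <= 0:
            raise ValueError("section thickness must be positive")
        if self.particle_height_um < 0:
            raise ValueError("particle height must be non-negative")
        if self.sampling_interval < 1:
            raise ValueError("sampling interval must be >= 1")


@dataclass
class CountEstimate:
    gene_id: str
    per_animal_totals: list[float]
    mean: float
    sd: float
    cv: float


@dataclass
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int

    @property
    def df(self) -> int:
        return self.n - 2


def abercrombie_correct(n: float, T: float, h: float) -> float:
    """Abercrombie's correction N = n * T / (T + h).

    With flat particles (h = 0) no profile is split and N = n; the
    correction decreases monotonically as particle height grows.
    """
    if n < 0 or T <= 0 or h < 0:
        raise ValueError("require n >= 0, T > 0, h >= 0")
    return n * T / (T + h)


def estimate_total(sections: SectionCounts) -> float:
    """Whole-structure total: stride times the Abercrombie-corrected sum of
    the counted sections."""
    corrected = sum(
        abercrombie_correct(
            c, sections.section_thickness_um, sections.particle_height_um
        )
        for c in sections.counts
    )
    return sections.sampling_interval * corrected


def summarize_counts(gene_id: str, per_animal_totals: list[float]) -> CountEstimate:
    """Mean, sample (n-1) SD and CV over per-animal totals."""
    totals = np.asarray(per_animal_totals, float)
    if totals.size < 2:
        raise ValueError("need at least two animals for an SD")
    mean = float(totals.mean())
    sd = float(totals.std(ddof=1))
    if mean == 0:
        if sd > 0:
            raise ValueError("CV undefined: zero mean with non-zero SD")
        cv = 0.0
    else:
        cv = sd / mean
    return CountEstimate(gene_id, list(map(float, totals)), mean, sd, cv)


def estimate_from_mean_sd(gene_id: str, mean: float, sd: float) -> CountEstimate:
    """Build a CountEstimate from a published mean +/- SD pair."""
    if mean <= 0 or sd < 0:
        raise ValueError("require mean > 0 and sd >= 0")
    return CountEstimate(gene_id, [], float(mean), float(sd), sd / mean)


def pearson_with_p(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p-value from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def load_reference_cell_counts() -> pd.DataFrame:
    """The shipped per-gene mean +/- SD table of solitary-gene cell counts
    (three-day-old mice, n = 3 animals)."""
    with resources.files("solor.data").joinpath("cell_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def mean_cv_correlation(table: pd.DataFrame | None = None) -> tuple[pd.DataFrame, CorrelationResult]:
    """Per-gene CVs and the average-vs-CV Pearson correlation.

    ``table`` needs columns gene, mean, sd; defaults to the shipped
    reference table.  Returns the table with a cv column added, plus the
    correlation of mean against CV.
    """
    if table is None:
        table = load_reference_cell_counts()
    out = table.copy()
    out["cv"] = [
        estimate_from_mean_sd(g, m, s).cv
        for g, m, s in zip(out["gene"], out["mean"], out["sd"])
    ]
    corr = pearson_with_p(out["mean"].to_numpy(), out["cv"].to_numpy())
    return out, corr
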