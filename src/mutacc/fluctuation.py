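"""Luria-Delbrück fluctuation-assay analysis.

Parallel cultures grown from small mutant-free inocula are plated on a
selective agent; the distribution of mutant counts across cultures follows
the Luria-Delbrück distribution, whose single parameter ``m`` is the
expected number of mutational events per culture.  Early ("jackpot")
mutations produce heavily skewed counts, which is why the mean mutant count
alone is uninformative and a likelihood fit is used.

The probability mass function is computed with the Ma-Sandri-Sarkar
recursion::

    p_0 = exp(-m)
    p_r = (m / r) * sum_{i=0}^{r-1} p_i / (r - i + 1)

and ``m`` is fit by maximising the log-likelihood of the observed counts
(MSS maximum-likelihood estimator).  A log-normal approximate 95%
confidence interval in the FALCOR/Stewart style is provided, with

    sigma_ln_m = 1.225 * m^(-0.315) / sqrt(C)

for ``C`` parallel cultures.  Rates convert as: per-locus rate
``m / N_final`` (``N_final`` viable cells per culture at plating), per
nucleotide after dividing by the number of resistance-conferring sites
(20 by default: 18 in *gyrA* plus 2 in *gyrB* for nalidixic acid), and per
genome after multiplying by genome size.

Classic assumptions: perfect plating, no phenotypic lag, mutant fitness
equal to wild type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NAL_R_TARGET_SITES",
    "FluctuationExperiment",
    "MSSMLEResult",
    "ld_pmf",
    "ld_log_likelihood",
    "mss_mle",
    "stewart_ci",
    "likelihood_ratio_ci",
    "convert_rate",
    "read_fluctuation_table",
    "write_fluctuation_table",
]

#: Nucleotides assumed able to confer nalidixic-acid resistance
#: (18 gyrA sites + 2 gyrB sites).
NAL_R_TARGET_SITES = 20

#: Mutant counts at or above this value are pooled into a single tail
#: category during likelihood evaluation; jackpot cultures otherwise
#: dominate runtime and numerics.
DEFAULT_COUNT_CAP = 150

_LN_M_LO, _LN_M_HI = math.log(1e-4), math.log(1e2)
_GOLDEN_TOL = 1e-6


@dataclass
class FluctuationExperiment:
    """Mutant counts from one fluctuation assay.

    ``mutant_counts`` has one entry per selective culture; ``final_cells``
    is the mean number of viable cells per culture from non-selective
    plating, needed only for rate conversion.
    """

    mutant_counts: np.ndarray
    final_cells: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mutant_counts = np.asarray(self.mutant_counts, dtype=int)
        if self.mutant_counts.ndim != 1 or self.mutant_counts.size == 0:
            raise ValueError("mutant_counts must be a non-empty vector")
        if np.any(self.mutant_counts < 0):
            raise ValueError("mutant counts are non-negative")
        if self.final_cells is not None and self.final_cells <= 0:
            raise ValueError("final_cells must be positive")

    @property
    def n_selective(self) -> int:
        return int(self.mutant_counts.size)


@dataclass(frozen=True)
class MSSMLEResult:
    """Fitted Luria-Delbrück parameter with confidence interval."""

    m_hat: float
    ci95: tuple[float, float] | None
    n_cultures: int
    log_likelihood: float
    unreliable: bool = False
    target_sites: int = NAL_R_TARGET_SITES


def ld_pmf(m: float, r_max: int) -> np.ndarray:
    """Luria-Delbrück probabilities ``p_0 .. p_r_max`` via the MSS recursion."""
    if m < 0:
        raise ValueError("LD parameter m must be non-negative")
    if r_max < 0:
        raise ValueError("r_max must be non-negative")
    p = np.zeros(r_max + 1)
    p[0] = math.exp(-m)
    for r in range(1, r_max + 1):
        # sum_{i=0}^{r-1} p_i / (r - i + 1)
        weights = 1.0 / (r - np.arange(r) + 1.0)
        p[r] = (m / r) * float(p[:r] @ weights)
    return p


def ld_log_likelihood(
    m: float, counts: np.ndarray, cap: int = DEFAULT_COUNT_CAP
) -> float:
    """Log-likelihood of observed counts; counts >= ``cap`` share the tail mass."""
    counts = np.asarray(counts, dtype=int)
    capped = np.minimum(counts, cap)
    if m == 0:
        return 0.0 if np.all(capped == 0) else -math.inf
    p = ld_pmf(m, cap)
    tail = max(1.0 - float(p[:cap].sum()), 1e-300)
    probs = np.where(capped >= cap, tail, np.maximum(p[capped], 1e-300))
    return float(np.log(probs).sum())


def _golden_section_max(f, lo: float, hi: float, tol: float) -> float:
    """Golden-section maximiser of a unimodal function on [lo, hi]."""
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2


def mss_mle(
    experiment: FluctuationExperiment,
    cap: int = DEFAULT_COUNT_CAP,
    compute_ci: bool = True,
) -> MSSMLEResult:
    """Fit the LD parameter ``m`` by MSS maximum likelihood.

    The likelihood is maximised by golden-section search on ``ln m`` over
    ``[1e-4, 1e2]`` to tolerance 1e-6; all-zero counts give the boundary
    estimate ``m_hat = 0``; an experiment whose counts all sit at the tail
    cap is flagged ``unreliable``.
    """
    counts = experiment.mutant_counts
    n = experiment.n_selective
    if np.all(counts == 0):
        return MSSMLEResult(0.0, None, n, 0.0, target_sites=NAL_R_TARGET_SITES)
    unreliable = bool(np.all(counts >= cap))

    def objective(ln_m: float) -> float:
        return ld_log_likelihood(math.exp(ln_m), counts, cap=cap)

    ln_m_hat = _golden_section_max(objective, _LN_M_LO, _LN_M_HI, _GOLDEN_TOL)
    m_hat = math.exp(ln_m_hat)
    ci = stewart_ci(m_hat, n) if compute_ci else None
    return MSSMLEResult(
        m_hat=m_hat,
        ci95=ci,
        n_cultures=n,
        log_likelihood=objective(ln_m_hat),
        unreliable=unreliable,
        target_sites=NAL_R_TARGET_SITES,
    )


def stewart_ci(m_hat: float, n_cultures: int) -> tuple[float, float]:
    """Approximate 95% CI on ``m``: log-normal with sigma = 1.225 m^-0.315 / sqrt(C).

    Asymmetric on the natural scale, symmetric in ``ln m``.
    """
    if m_hat <= 0:
        raise ValueError("confidence interval undefined for m_hat = 0")
    if n_cultures < 1:
        raise ValueError("need at least one culture")
    sigma = 1.225 * m_hat ** (-0.315) / math.sqrt(n_cultures)
    return (m_hat * math.exp(-1.96 * sigma), m_hat * math.exp(1.96 * sigma))


def likelihood_ratio_ci(
    experiment: FluctuationExperiment,
    m_hat: float,
    cap: int = DEFAULT_COUNT_CAP,
) -> tuple[float, float]:
    """95% profile-likelihood interval: ln L drops by chi2_{1,0.95}/2 = 1.92."""
    if m_hat <= 0:
        raise ValueError("likelihood-ratio interval undefined for m_hat = 0")
    counts = experiment.mutant_counts
    target = ld_log_likelihood(m_hat, counts, cap=cap) - 1.9207
    grid = np.exp(np.linspace(_LN_M_LO, _LN_M_HI, 2000))
    ll = np.array([ld_log_likelihood(m, counts, cap=cap) for m in grid])
    inside = grid[ll >= target]
    if inside.size == 0:
        return (m_hat, m_hat)
    return (float(inside.min()), float(inside.max()))


def convert_rate(
    result: MSSMLEResult,
    final_cells: float,
    target_sites: int = NAL_R_TARGET_SITES,
    genome_size: float | None = None,
) -> dict[str, float]:
    """Convert a fitted ``m`` into mutation rates.

    per-locus rate = m_hat / final_cells (per culture-division);
    per-nucleotide = per-locus / target_sites; per-genome = per-nucleotide
    × genome_size.  Confidence limits convert identically when present.
    """
    if final_cells <= 0:
        raise ValueError("final_cells must be positive")
    if target_sites <= 0:
        raise ValueError("target_sites must be positive")
    per_locus = result.m_hat / final_cells
    rates = {
        "per_locus": per_locus,
        "per_nucleotide": per_locus / target_sites,
    }
    if genome_size is not None:
        rates["per_genome"] = rates["per_nucleotide"] * genome_size
    if result.ci95 is not None:
        lo, hi = result.ci95
        rates["per_locus_ci95"] = (lo / final_cells, hi / final_cells)
    return rates


# -- I/O -------------------------------------------------------------------


def read_fluctuation_table(
    source: str | Path, final_cells: float | None = None
) -> FluctuationExperiment:
    """Read a two-column table (culture_id, mutant_count), tab-delimited."""
    frame = pd.read_csv(source, sep="\t")
    if "mutant_count" not in frame.columns:
        raise ValueError("fluctuation table needs a 'mutant_count' column")
    return FluctuationExperiment(
        mutant_counts=frame["mutant_count"].to_numpy(dtype=int),
        final_cells=final_cells,
    )


def write_fluctuation_table(
    experiment: FluctuationExperiment, path: str | Path
) -> None:
    pd.DataFrame(
        {
            "culture_id": [f"c{i+1:03d}" for i in range(experiment.n_selective)],
            "mutant_count": experiment.mutant_counts,
        }
    ).to_csv(path, sep="\t", index=False)
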