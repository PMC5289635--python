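"""Mutational-spectrum summaries and positional null-model tests.

Covers four questions about where and how substitutions fall:

* the transition:transversion ratio of the BPS spectrum;
* replichore strand bias — for a given pair class and top-strand focal
  base, are substitutions split between the clockwise and counter-clockwise
  replichores as their sizes (or focal-base compositions) predict under
  equal leading/lagging-strand mutability?  Because the top strand templates
  the lagging strand on the clockwise replichore and the leading strand on
  the counter-clockwise one, an uneven split signals a strand-asymmetric
  mutational mechanism;
* macrodomain placement — are mutations of a class spread over the
  chromosome's macrodomains in proportion to their lengths?
* cumulative position curves for visual comparison against uniformity.

All tests are Pearson chi-square goodness-of-fit tests without continuity
correction, and p-values are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import CLOCKWISE, COUNTER_CLOCKWISE, GenomeModel
from .mutation_catalog import (
    MutationSet,
    TRANSITION_CLASSES,
    TRANSVERSION_CLASSES,
    classify_bps,
)

__all__ = [
    "InfiniteRatioError",
    "StrandBiasTable",
    "ts_tv_ratio",
    "replichore_counts",
    "expected_replichore_split",
    "chi_square_gof",
    "strand_bias_test",
    "macrodomain_test",
    "cumulative_positions",
]


class InfiniteRatioError(ZeroDivisionError):
    """Raised when a ratio's denominator class has zero observations."""


def ts_tv_ratio(mset: MutationSet, environment: str | None = None) -> float:
    """Transition:transversion ratio over the BPS records.

    Transitions are the two purine↔purine / pyrimidine↔pyrimidine classes
    (A:T>G:C and G:C>A:T); the other four classes are transversions.
    """
    sub = mset.filter(environment=environment, mclass="BPS")
    ts = sum(1 for r in sub if r.pair_class in TRANSITION_CLASSES)
    tv = sum(1 for r in sub if r.pair_class in TRANSVERSION_CLASSES)
    if tv == 0:
        raise InfiniteRatioError(
            f"no transversions observed ({ts} transitions); ratio is infinite"
        )
    return ts / tv


def replichore_counts(
    mset: MutationSet,
    pair_class: str,
    focal_base: str,
    model: GenomeModel,
    environment: str | None = None,
) -> tuple[int, int]:
    """Observed (clockwise, counter-clockwise) counts for one orientation.

    Selects BPS records of ``pair_class`` whose literal top-strand reference
    base is ``focal_base`` and splits them by replichore.
    """
    cw = ccw = 0
    for rec in mset.filter(environment=environment, mclass="BPS"):
        if rec.pair_class != pair_class or rec.ref_base != focal_base.upper():
            continue
        if model.replichore_of(rec.position) == CLOCKWISE:
            cw += 1
        else:
            ccw += 1
    return cw, ccw


def expected_replichore_split(
    total: int,
    model: GenomeModel,
    mode: str = "length",
    focal_base: str | None = None,
) -> tuple[float, float]:
    """Expected (clockwise, counter-clockwise) counts under no strand bias.

    ``mode='length'`` allocates ``total`` proportionally to the replichore
    arc lengths (the published construction); ``mode='composition'``
    allocates proportionally to the top-strand count of ``focal_base``
    within each replichore, correcting for compositional skew between arms.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    if mode == "length":
        reps = model.replichores
        w_cw = reps[CLOCKWISE][2]
        w_ccw = reps[COUNTER_CLOCKWISE][2]
    elif mode == "composition":
        if focal_base is None:
            raise ValueError("composition mode requires a focal_base")
        base = focal_base.upper()
        w_cw = model.base_counts(CLOCKWISE)[base]
        w_ccw = model.base_counts(COUNTER_CLOCKWISE)[base]
        if w_cw + w_ccw == 0:
            raise ValueError(f"genome contains no {base} bases")
    else:
        raise ValueError(f"unknown expectation mode {mode!r}")
    w = w_cw + w_ccw
    return total * w_cw / w, total * w_ccw / w


def chi_square_gof(
    observed: Sequence[float], expected: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit: sum (O-E)^2/E, df = k-1, upper-tail p."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have the same length")
    if np.any(exp <= 0):
        raise ValueError("all expected counts must be positive")
    statistic = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    if df < 1:
        raise ValueError("goodness-of-fit needs at least two categories")
    return statistic, df, float(stats.chi2.sf(statistic, df))


@dataclass(frozen=True)
class StrandBiasTable:
    """One pair-class/focal-base strand-bias test (1 df)."""

    pair_class: str
    focal_base: str
    observed: tuple[int, int]
    expected: tuple[float, float]
    chi_square: float
    df: int
    p: float
    mode: str


def strand_bias_test(
    mset: MutationSet,
    pair_class: str,
    focal_base: str,
    model: GenomeModel,
    environment: str | None = None,
    mode: str = "length",
) -> StrandBiasTable:
    """Replichore strand-bias chi-square for one substitution orientation."""
    observed = replichore_counts(mset, pair_class, focal_base, model, environment)
    total = sum(observed)
    expected = expected_replichore_split(total, model, mode=mode, focal_base=focal_base)
    statistic, df, p = chi_square_gof(observed, expected)
    return StrandBiasTable(
        pair_class=pair_class,
        focal_base=focal_base.upper(),
        observed=observed,
        expected=expected,
        chi_square=statistic,
        df=df,
        p=p,
        mode=mode,
    )


def macrodomain_test(
    mset: MutationSet,
    model: GenomeModel,
    mclass: str | None = None,
    environment: str | None = None,
) -> tuple[float, int, float, pd.DataFrame]:
    """Chi-square test of even mutation placement across macrodomains.

    Expected counts are proportional to macrodomain lengths; df is the
    number of macrodomains minus one.  Returns the statistic, df, p and the
    observed/expected table.
    """
    lengths = model.macrodomain_lengths()
    if len(lengths) < 2:
        raise ValueError("macrodomain test needs at least two macrodomains")
    names = list(lengths)
    observed = dict.fromkeys(names, 0)
    for rec in mset.filter(environment=environment, mclass=mclass):
        observed[model.macrodomain_of(rec.position)] += 1
    total = sum(observed.values())
    genome = sum(lengths.values())
    expected = {n: total * lengths[n] / genome for n in names}
    statistic, df, p = chi_square_gof(
        [observed[n] for n in names], [expected[n] for n in names]
    )
    table = pd.DataFrame(
        {
            "macrodomain": names,
            "length_bp": [lengths[n] for n in names],
            "observed": [observed[n] for n in names],
            "expected": [expected[n] for n in names],
        }
    )
    return statistic, df, p, table


def cumulative_positions(
    mset: MutationSet,
    mclass: str | None = None,
    environment: str | None = None,
) -> pd.DataFrame:
    """Sorted positions with cumulative counts (uniformity-curve data).

    Two columns, ``position`` and ``cumulative``; the curve is monotone
    non-decreasing and ends at the number of selected records.
    """
    positions = sorted(
        r.position for r in mset.filter(environment=environment, mclass=mclass)
    )
    return pd.DataFrame(
        {"position": positions, "cumulative": np.arange(1, len(positions) + 1)}
    )
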