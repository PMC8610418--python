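"""Colony-count arithmetic: mutation frequencies, rates and survival.

A fluctuation assay grows many parallel cultures from small inocula, plates
each on selective medium (canavanine, selecting CAN1 loss-of-function) and on
permissive medium at high dilution, and counts colonies.  The per-culture
mutant *frequency* is resistant colonies divided by viable cells plated; the
mutation *rate* (mutations per cell per generation) must account for the
jackpot-skewed Luria-Delbrück distribution of resistant counts, here via the
Lea-Coulson method of the median: the expected number of mutation events per
culture m solves

    r_median / m - ln(m) = 1.24

and the rate is mu = m / N with N the final cells per culture.  Confidence
limits use the log-normal approximation sigma_ln(m) = 1.225 m^-0.315 / sqrt(C)
over C cultures.  Survival assays reduce to percentages of an untreated
control and ratios thereof.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

LEA_COULSON_CONSTANT = 1.24


def mutation_frequency(
    canr_colonies: float, sc_colonies: float, dilution: float
) -> float:
    """Mutant frequency: resistant colonies / (permissive colonies x dilution).

    ``sc_colonies`` is the colony count on permissive plates seeded with a
    1/``dilution`` aliquot of the culture, so the denominator estimates the
    viable cells plated on the selective plate.
    """
    if sc_colonies <= 0:
        raise ValueError("permissive-plate colony count must be > 0")
    if dilution <= 0:
        raise ValueError("dilution factor must be > 0")
    if canr_colonies < 0:
        raise ValueError("colony counts must be >= 0")
    return canr_colonies / (sc_colonies * dilution)


def lea_coulson_m(r_median: float) -> float:
    """Solve r_median/m - ln(m) = 1.24 for the mutation events per culture m."""
    if r_median <= 0:
        raise ValueError("median resistant count must be > 0")

    def g(log_m: float) -> float:
        m = np.exp(log_m)
        return r_median / m - log_m - LEA_COULSON_CONSTANT

    # g is strictly decreasing in m; bracket in log space
    lo, hi = -30.0, 30.0
    return float(np.exp(optimize.brentq(g, lo, hi, xtol=1e-12)))


@dataclass
class RateEstimate:
    mu: float
    ci_low: float
    ci_high: float
    estimator: str
    n_cultures: int
    is_upper_bound: bool = False

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("rate must be >= 0")


def frequency_to_rate(
    resistant_counts,
    n_cells: float,
    estimator: str = "lea_coulson",
) -> RateEstimate:
    """Per-experiment mutation rate from per-culture resistant counts.

    ``lea_coulson`` (default): method of the median, mu = m / N.  With a zero
    median the estimate degenerates; an upper bound is returned from the
    requirement that C cultures with zero median would be seen with >= 5%
    probability under a Poisson number of mutation events, flagged as such.

    ``frequency``: median per-culture frequency r / N, a biased but
    assumption-free summary provided for comparison.
    """
    counts = np.asarray(list(resistant_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("need >= 1 culture")
    if (counts < 0).any():
        raise ValueError("resistant counts must be >= 0")
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    C = counts.size
    r_median = float(np.median(counts))

    if estimator == "frequency":
        mu = r_median / n_cells
        return RateEstimate(mu, np.nan, np.nan, "frequency", C)
    if estimator != "lea_coulson":
        raise ValueError(f"unknown estimator {estimator!r}")

    if r_median == 0:
        # at least half the cultures had zero mutants; bound m by requiring
        # P(>= C/2 zero cultures) not implausibly small: exp(-m) >= 0.5 per
        # culture gives m <= ln 2 at the median; report the Poisson bound
        m_upper = -np.log(0.05) / C
        return RateEstimate(
            m_upper / n_cells, 0.0, m_upper / n_cells,
            "lea_coulson (p0 upper bound)", C, is_upper_bound=True,
        )

    m = lea_coulson_m(r_median)
    sigma = 1.225 * m ** (-0.315) / np.sqrt(C)
    ci = (np.exp(np.log(m) - 1.96 * sigma), np.exp(np.log(m) + 1.96 * sigma))
    return RateEstimate(
        mu=m / n_cells, ci_low=ci[0] / n_cells, ci_high=ci[1] / n_cells,
        estimator="lea_coulson", n_cultures=C,
    )


def experiment_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a plate-level colony table to one row per culture.

    Expected columns: culture, medium ("selective"/"permissive"), plate,
    dilution, colonies.  Duplicate plates of the same culture and medium are
    averaged; the per-culture frequency is added.
    """
    required = {"culture", "medium", "dilution", "colonies"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    means = (
        table.groupby(["culture", "medium"])
        .agg(colonies=("colonies", "mean"), dilution=("dilution", "first"))
        .reset_index()
        .pivot(index="culture", columns="medium", values=["colonies", "dilution"])
    )
    out = pd.DataFrame(
        {
            "canr_colonies": means[("colonies", "selective")],
            "sc_colonies": means[("colonies", "permissive")],
            "sc_dilution": means[("dilution", "permissive")],
        }
    ).reset_index()
    out["frequency"] = [
        mutation_frequency(r.canr_colonies, r.sc_colonies, r.sc_dilution)
        if r.sc_colonies > 0 else np.nan
        for r in out.itertuples()
    ]
    return out


def survival_percent(colonies_treated: float, colonies_untreated: float) -> float:
    """Colonies after treatment as a percentage of the untreated control."""
    if colonies_untreated <= 0:
        raise ValueError("untreated colony count must be > 0")
    if colonies_treated < 0:
        raise ValueError("colony counts must be >= 0")
    return 100.0 * colonies_treated / colonies_untreated


def fold_rescue(survival_a: float, survival_b: float) -> float:
    """Ratio of two survival percentages (rescue construct vs control)."""
    if survival_b <= 0:
        raise ValueError("denominator survival must be > 0")
    if survival_a < 0:
        raise ValueError("survival must be >= 0")
    return survival_a / survival_b
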