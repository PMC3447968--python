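"""Decoupling interaction conservation from interactome coverage.

The observed fraction of correct inferences from species s to species t
factorizes as

    f_obs(s -> t) = f_true(s, t) * c_t                                (model)

where f_true is the fraction of inferences that are genuinely conserved and
c_t is the coverage of the target species' interaction data (one minus its
false-negative rate). The twelve ordered-pair equations have more unknowns
than equations, so two assumptions close the system: a designated reference
species' interactome is complete (c_ref = 1; altering this rescales every
result by a constant multiple), and conservation is symmetric with the
reference, f_true(t, ref) = f_true(ref, t). Then

    f_true(t, ref) = f_obs(t -> ref),
    c_t            = f_obs(ref -> t) / f_obs(t -> ref),
    size_t         = observed interaction count of t / c_t,

and for non-reference pairs f_true(s, t) = f_obs(s -> t) / c_t (the target's
coverage only; a symmetrized alternative is conceivable but not used --
flagged in the output metadata). Coverage estimates above 1 diagnose
violated assumptions (typically reporting bias) and are flagged, never
clipped.

Finally, if an interaction present in the two species' last common ancestor
is lost independently with probability q per million years in each lineage,
the probability that both species retain it after T million years of
divergence is f = (1 - q)^(2T), inverted as q = 1 - f^(1/(2T)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import pandas as pd


@dataclass
class ConservationEstimate:
    source: str
    target: str
    f_obs_st: float  # f_obs(source -> target)
    f_obs_ts: Optional[float]  # f_obs(target -> source), when available
    f_true: float
    c_t: float  # estimated coverage of the target species
    n_observed_t: Optional[int]
    interactome_size: Optional[float]  # n_observed_t / c_t
    reference: str
    threshold: Optional[float] = None
    coverage_violation: bool = False  # c_t > 1: assumption violated upstream
    f_true_convention: str = "target-coverage-only"


def estimate_coverage_and_conservation(
    f_obs: Mapping[tuple[str, str], float],
    observed_counts: Mapping[str, int],
    reference: str,
    threshold: Optional[float] = None,
) -> list[ConservationEstimate]:
    """Solve the coverage model for every species pair in ``f_obs``.

    ``f_obs`` maps ordered (source, target) pairs to observed fractions of
    correct inferences; both directions with the reference must be present
    and positive for every non-reference species.
    """
    species = sorted({s for pair in f_obs for s in pair})
    if reference not in species:
        raise ValueError(f"reference species {reference!r} absent from f_obs")
    coverages: dict[str, float] = {reference: 1.0}
    estimates: list[ConservationEstimate] = []
    for t in species:
        if t == reference:
            continue
        if (reference, t) not in f_obs or (t, reference) not in f_obs:
            raise ValueError(f"f_obs missing for the ({reference}, {t}) pair")
        f_rt, f_tr = f_obs[(reference, t)], f_obs[(t, reference)]
        if f_tr <= 0:
            raise ValueError(
                f"f_obs({t} -> {reference}) = 0: coverage of {t} undefined"
            )
        c_t = f_rt / f_tr
        coverages[t] = c_t
        n_obs = observed_counts.get(t)
        estimates.append(
            ConservationEstimate(
                source=reference,
                target=t,
                f_obs_st=f_rt,
                f_obs_ts=f_tr,
                f_true=f_tr,  # symmetric-with-reference assumption
                c_t=c_t,
                n_observed_t=n_obs,
                interactome_size=(n_obs / c_t if n_obs is not None else None),
                reference=reference,
                threshold=threshold,
                coverage_violation=c_t > 1.0,
            )
        )
    for (s, t), f_st in sorted(f_obs.items()):
        if reference in (s, t) or t not in coverages:
            continue
        c_t = coverages[t]
        n_obs = observed_counts.get(t)
        estimates.append(
            ConservationEstimate(
                source=s,
                target=t,
                f_obs_st=f_st,
                f_obs_ts=f_obs.get((t, s)),
                f_true=f_st / c_t,
                c_t=c_t,
                n_observed_t=n_obs,
                interactome_size=(n_obs / c_t if n_obs is not None else None),
                reference=reference,
                threshold=threshold,
                coverage_violation=c_t > 1.0,
            )
        )
    return estimates


def sweep_estimates(
    f_obs_by_threshold: Mapping[float, Mapping[tuple[str, str], float]],
    observed_counts: Mapping[str, int],
    reference: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-threshold estimates plus mean/sd over the threshold sweep.

    Returns (per-threshold table, aggregate table); the aggregate follows
    the convention of reporting each quantity's mean and standard deviation
    across the E-value thresholds investigated.
    """
    rows = []
    for threshold in sorted(f_obs_by_threshold):
        for est in estimate_coverage_and_conservation(
            f_obs_by_threshold[threshold], observed_counts, reference, threshold
        ):
            rows.append(vars(est).copy())
    per_threshold = pd.DataFrame(rows)
    agg = (
        per_threshold.groupby(["source", "target"], as_index=False)
        .agg(
            f_true_mean=("f_true", "mean"),
            f_true_sd=("f_true", "std"),
            coverage_mean=("c_t", "mean"),
            coverage_sd=("c_t", "std"),
            size_mean=("interactome_size", "mean"),
            size_sd=("interactome_size", "std"),
            n_thresholds=("threshold", "count"),
        )
    )
    return per_threshold, agg


def rescale_reference(
    estimates: Sequence[ConservationEstimate], reference_coverage: float
) -> list[ConservationEstimate]:
    """Propagate a non-complete reference interactome through the estimates.

    With c_ref = r instead of 1, every coverage is multiplied by r, every
    conserved fraction by 1/r and every interactome size by 1/r, so the
    model identity f_obs = f_true * c is preserved exactly.
    """
    if not 0 < reference_coverage <= 1:
        raise ValueError("reference_coverage must be in (0, 1]")
    r = reference_coverage
    out = []
    for est in estimates:
        c_t = est.c_t * r
        out.append(
            replace(
                est,
                c_t=c_t,
                f_true=est.f_true / r,
                interactome_size=(
                    est.interactome_size / r
                    if est.interactome_size is not None else None
                ),
                coverage_violation=c_t > 1.0,
            )
        )
    return out


@dataclass
class LossRateEstimate:
    q: float  # probability per unit time that a lineage loses the interaction
    q_low: Optional[float]
    q_high: Optional[float]
    T: float  # divergence time, million years
    T_range: Optional[tuple[float, float]]
    f_true: float


def loss_rate(
    f_true: float, T: float, T_range: Optional[tuple[float, float]] = None
) -> LossRateEstimate:
    """Invert f = (1 - q)^(2T) for the per-unit-time loss probability q.

    ``f_true`` is the probability that an ancestral interaction is retained
    in both lineages after T units of divergence. Larger divergence times
    give smaller loss rates, so the reported range pairs q_low with the
    upper end of ``T_range``.
    """
    if not 0 < f_true <= 1:
        raise ValueError("f_true must be in (0, 1]")
    if T <= 0:
        raise ValueError("T must be positive")

    def q_of(t: float) -> float:
        return 1.0 - f_true ** (1.0 / (2.0 * t))

    q_low = q_high = None
    if T_range is not None:
        t_lo, t_hi = T_range
        if not 0 < t_lo <= t_hi:
            raise ValueError("T_range must satisfy 0 < low <= high")
        q_low, q_high = q_of(t_hi), q_of(t_lo)
    return LossRateEstimate(q_of(T), q_low, q_high, T, T_range, f_true)
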