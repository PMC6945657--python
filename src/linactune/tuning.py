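"""Beam-parameter tuning decision procedures.

Two low-statistics decision rules drive the truncated fine-tuning workflow:

1. **Initial-energy selection by trend.**  For each candidate initial
   electron energy, the PDD is simulated at an increasing ladder of
   history counts and compared to the measured PDD.  A candidate that
   matches the measurement shows 1%/1mm passing rates that rise as the
   statistical uncertainty falls: the Pearson correlation r between
   average uncertainty and passing rate is strongly negative.  A candidate
   qualifies when r <= -0.80 and its final 1%/1mm rate is >= 80%.

2. **Three-stage serial profile optimization.**  With the energy fixed,
   the energy FWHM, focal-spot FWHM and divergence are optimized one at a
   time (remaining parameters at zero), each stage picking the candidate
   with the highest 1%/1mm passing rate against the measured lateral
   profiles and feeding it to the next stage.  An optional cross-depth
   safeguard compares the top two candidates of stage one across all scan
   depths and overturns the pick if the runner-up wins a majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .beam import BeamConfig, PhantomSpec
from .curves import ScanCurve, extract_pdd, extract_profile
from .gamma import CRITERIA_1_1, GammaCriteria, gamma_curve, multi_criteria_report
from .simulate import (
    DEFAULT_CONSTANTS,
    ModelConstants,
    ReferenceScans,
    average_uncertainty,
    generate_dose_grid,
    generate_dose_grid_ladder,
)

__all__ = [
    "TrendRow",
    "TrendRecord",
    "StageResult",
    "DepthComparison",
    "EnergySelection",
    "TuningOutcome",
    "Simulator",
    "pearson",
    "build_trend",
    "select_energy",
    "stage_argmax",
    "cross_depth_compare",
    "run_energy_sweep",
    "run_staged_tuning",
    "derive_seed",
    "DEFAULT_HISTORY_LADDER",
]

STAGE_PARAMETERS = ("energy_fwhm", "focal_spot_fwhm", "divergence")


def pearson(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two sequences.

    Requires equal lengths >= 3 and nonzero variance in each column.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be equal-length 1D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: a column has zero variance")
    return float(scipy.stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class TrendRow:
    """One rung of a history sweep: histories, average uncertainty, rates."""

    n_histories: int
    avg_uncertainty: float
    rate_3_3: float
    rate_2_2: float
    rate_1_1: float


@dataclass(frozen=True)
class TrendRecord:
    """A candidate energy's history sweep with its Pearson trend.

    ``pearson_r`` correlates the average-uncertainty column with the
    1%/1mm passing-rate column; ``final_rate_1_1`` is the 1%/1mm rate of
    the highest-statistics rung.
    """

    candidate_label: str
    energy: float
    rows: tuple
    pearson_r: float

    @property
    def final_rate_1_1(self) -> float:
        return self.rows[-1].rate_1_1


def build_trend(candidate_label: str, sweep, energy: float = float("nan")) -> TrendRecord:
    """Assemble a TrendRecord from (n_histories, avg_uncertainty, (r33, r22, r11)) rows."""
    rows = []
    for n, unc, rates in sweep:
        r33, r22, r11 = rates
        rows.append(TrendRow(int(n), float(unc), float(r33), float(r22), float(r11)))
    if len(rows) < 3:
        raise ValueError("need at least 3 sweep rows")
    ns = [r.n_histories for r in rows]
    if any(b <= a for a, b in zip(ns, ns[1:])):
        raise ValueError("sweep rows must be ordered by increasing n_histories")
    r = pearson([r.avg_uncertainty for r in rows], [r.rate_1_1 for r in rows])
    return TrendRecord(candidate_label, energy, tuple(rows), r)


@dataclass(frozen=True)
class EnergySelection:
    """Outcome of trend-based initial-energy selection."""

    chosen: Optional[TrendRecord]
    qualifiers: tuple
    diagnostics: tuple  # of (label, pearson_r, final_rate_1_1, qualifies)
    r_threshold: float
    rate_threshold: float

    @property
    def chosen_label(self) -> Optional[str]:
        return self.chosen.candidate_label if self.chosen else None

    @property
    def chosen_energy(self) -> Optional[float]:
        return self.chosen.energy if self.chosen else None


def select_energy(
    trends: Sequence[TrendRecord],
    r_threshold: float = -0.80,
    rate_threshold: float = 80.0,
) -> EnergySelection:
    """Select the initial electron energy from candidate trend records.

    A candidate qualifies when its Pearson r is at least as negative as
    ``r_threshold`` and its final 1%/1mm rate reaches ``rate_threshold``.
    Among qualifiers the most negative r wins; ties break to the higher
    final rate.  With no qualifier the selection is empty and the
    diagnostics carry the per-candidate numbers (the practical advice is
    then to extend the history ladder).
    """
    if not trends:
        raise ValueError("no candidate trends supplied")
    diagnostics = tuple(
        (t.candidate_label, t.pearson_r, t.final_rate_1_1,
         t.pearson_r <= r_threshold and t.final_rate_1_1 >= rate_threshold)
        for t in trends
    )
    qualifiers = tuple(t for t, d in zip(trends, diagnostics) if d[3])
    chosen = None
    if qualifiers:
        chosen = min(qualifiers, key=lambda t: (t.pearson_r, -t.final_rate_1_1))
    return EnergySelection(chosen, qualifiers, diagnostics, r_threshold, rate_threshold)


@dataclass(frozen=True)
class StageResult:
    """Result of one serial-optimization stage.

    ``best_depth_rates`` holds, per candidate, the highest 1%/1mm rate over
    the scan depths; the chosen candidate attains the maximum of these
    (ties toward the smallest parameter value).
    """

    parameter_name: str
    candidates: tuple
    best_depth_rates: tuple
    chosen_value: float
    chosen_rate: float
    per_depth_rates: tuple = field(default=(), repr=False)


def stage_argmax(parameter_name: str, candidates, per_depth_rates) -> StageResult:
    """Pick the candidate whose best scan depth has the highest 1%/1mm rate.

    ``per_depth_rates[i]`` lists candidate i's rates at each scan depth.
    Ties break toward the smaller parameter value.
    """
    cands = tuple(float(c) for c in candidates)
    if not cands or len(cands) != len(per_depth_rates):
        raise ValueError("candidates and per_depth_rates must align and be nonempty")
    table = tuple(tuple(float(r) for r in row) for row in per_depth_rates)
    if any(not row for row in table):
        raise ValueError("each candidate needs at least one depth rate")
    best = tuple(max(row) for row in table)
    order = sorted(range(len(cands)), key=lambda i: (-best[i], cands[i]))
    i = order[0]
    return StageResult(parameter_name, cands, best, cands[i], best[i], table)


@dataclass(frozen=True)
class DepthComparison:
    """Cross-depth head-to-head of two candidates' 1%/1mm rates."""

    label_a: str
    label_b: str
    rates_a: tuple
    rates_b: tuple
    wins_a: int
    wins_b: int
    ties: int
    winner: str
    depths: tuple = ()


def cross_depth_compare(label_a, rates_a, label_b, rates_b, depths=()) -> DepthComparison:
    """Count, per scan depth, which candidate's 1%/1mm rate is strictly higher.

    The majority of depths wins; equal counts break to the higher single
    best-depth rate; a full tie goes to the first-declared candidate.
    """
    ra = tuple(float(r) for r in rates_a)
    rb = tuple(float(r) for r in rates_b)
    if len(ra) != len(rb) or not ra:
        raise ValueError("per-depth rate lists must be nonempty and equal length")
    wins_a = sum(a > b for a, b in zip(ra, rb))
    wins_b = sum(b > a for a, b in zip(ra, rb))
    ties = len(ra) - wins_a - wins_b
    if wins_a != wins_b:
        winner = label_a if wins_a > wins_b else label_b
    elif max(ra) != max(rb):
        winner = label_a if max(ra) > max(rb) else label_b
    else:
        winner = label_a
    return DepthComparison(label_a, label_b, ra, rb, wins_a, wins_b, ties, winner,
                           tuple(depths))


def derive_seed(master_seed: int, *indices: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and indices."""
    ss = np.random.SeedSequence([int(master_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class Simulator:
    """Handle binding the synthetic dose engine to a phantom and constants."""

    phantom: PhantomSpec = PhantomSpec()
    constants: ModelConstants = DEFAULT_CONSTANTS

    def run(self, config: BeamConfig, n_histories: int, seed: int):
        return generate_dose_grid(
            config, self.phantom, n_histories, seed, self.constants
        )

    def run_ladder(self, config: BeamConfig, history_ladder, seed: int):
        """One accumulating run yielding a grid per ladder rung."""
        return generate_dose_grid_ladder(
            config, self.phantom, history_ladder, seed, self.constants
        )


DEFAULT_HISTORY_LADDER = (
    2_000_000, 10_000_000, 25_000_000, 50_000_000, 75_000_000, 100_000_000,
)


def run_energy_sweep(
    simulator: Simulator,
    reference_pdd: ScanCurve,
    candidates: Sequence[float],
    history_ladder: Sequence[int] = DEFAULT_HISTORY_LADDER,
    master_seed: int = 0,
    replicates: int = 4,
    labels: Optional[Sequence[str]] = None,
) -> list[TrendRecord]:
    """History sweep of candidate initial energies against a reference PDD.

    Each candidate (other beam parameters at zero) is simulated as
    ``replicates`` independent accumulating runs; within a run the ladder
    rungs share nested noise, emulating a Monte-Carlo simulation that is
    resumed to higher history counts.  Per rung, the PDD is extracted,
    compared at the three criteria, and the rates and average uncertainty
    are averaged over replicates before the Pearson trend is taken —
    without the replicate averaging the trend statistic is dominated by
    the rung-to-rung scatter of the passing rate.  Seeds derive from
    (candidate index, replicate index, master seed).

    Energy selection deliberately consumes only PDD comparisons: lateral
    profiles do not discriminate the initial energy.
    """
    ladder = [int(n) for n in history_ladder]
    if len(ladder) < 3:
        raise ValueError("history ladder needs at least 3 rungs")
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("history ladder must be strictly increasing")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if labels is None:
        labels = [f"{e:g} MeV" for e in candidates]
    trends = []
    for ci, energy in enumerate(candidates):
        config = BeamConfig(energy=float(energy))
        uncs = np.zeros(len(ladder))
        rates = np.zeros((len(ladder), 3))
        for rep in range(replicates):
            seed = derive_seed(master_seed, ci, rep)
            for ri, grid in enumerate(simulator.run_ladder(config, ladder, seed)):
                uncs[ri] += average_uncertainty(grid, simulator.constants.unc_threshold)
                report = multi_criteria_report(reference_pdd, extract_pdd(grid))
                rates[ri] += np.asarray(report.as_tuple())
        uncs /= replicates
        rates /= replicates
        sweep = [
            (n, uncs[ri], tuple(rates[ri])) for ri, n in enumerate(ladder)
        ]
        trends.append(build_trend(labels[ci], sweep, energy=float(energy)))
    return trends


@dataclass(frozen=True)
class TuningOutcome:
    """Final configuration plus the full audit trail of the serial stages."""

    final_config: BeamConfig
    stages: tuple  # of StageResult, in execution order
    depth_comparison: Optional[DepthComparison] = None


def _stage_rates(
    simulator: Simulator,
    reference: ReferenceScans,
    config: BeamConfig,
    n_histories: int,
    seed: int,
    criteria: GammaCriteria,
) -> list[float]:
    """1%/1mm rate per reference scan depth for one candidate configuration."""
    grid = simulator.run(config, n_histories, seed)
    rates = []
    for depth, ref_curve in reference.profiles:
        evaluated = extract_profile(grid, depth)
        rates.append(gamma_curve(ref_curve, evaluated, criteria).passing_rate)
    return rates


def run_staged_tuning(
    simulator: Simulator,
    reference: ReferenceScans,
    energy_fixed: float,
    grids: dict,
    n_histories: int = 25_000_000,
    master_seed: int = 0,
    seed_policy: str = "shared",
    criteria: GammaCriteria = CRITERIA_1_1,
    cross_depth_check: bool = False,
) -> TuningOutcome:
    """Serially optimize energy FWHM, focal-spot FWHM and divergence.

    Stage 1 varies the energy FWHM with focal spot and divergence at zero;
    stage 2 fixes the winner and varies the focal spot (divergence zero);
    stage 3 varies the divergence.  Each stage simulates every candidate at
    ``n_histories`` and applies :func:`stage_argmax` to the 1%/1mm rates
    against the reference lateral profiles.

    ``seed_policy`` is 'shared' (all candidates within a stage reuse one
    noise realization — common random numbers, so candidate comparisons
    are not washed out by independent noise) or 'independent' (a fresh
    realization per candidate, as separate MC runs would give).

    With ``cross_depth_check`` the top two stage-1 candidates are compared
    depth-by-depth and the pick is overturned when the runner-up wins a
    majority of depths, before stages 2 and 3 proceed.
    """
    if seed_policy not in ("shared", "independent"):
        raise ValueError("seed_policy must be 'shared' or 'independent'")
    missing = [p for p in STAGE_PARAMETERS if not grids.get(p)]
    if missing:
        raise ValueError(f"empty candidate grid(s): {missing}")

    current = BeamConfig(energy=float(energy_fixed))
    stages = []
    depth_cmp = None
    for si, param in enumerate(STAGE_PARAMETERS):
        candidates = [float(v) for v in grids[param]]
        per_depth = []
        for ci, value in enumerate(candidates):
            config = current.with_(**{param: value})
            seed = (
                derive_seed(master_seed, si)
                if seed_policy == "shared"
                else derive_seed(master_seed, si, ci)
            )
            try:
                per_depth.append(
                    _stage_rates(simulator, reference, config, n_histories, seed, criteria)
                )
            except Exception as exc:  # re-raise with stage context
                raise RuntimeError(
                    f"simulation failed at stage {si + 1} ({param}={value})"
                ) from exc
        stage = stage_argmax(param, candidates, per_depth)
        chosen_value = stage.chosen_value
        if cross_depth_check and si == 0 and len(candidates) >= 2:
            order = sorted(
                range(len(candidates)),
                key=lambda i: (-stage.best_depth_rates[i], candidates[i]),
            )
            a, b = order[0], order[1]
            depth_cmp = cross_depth_compare(
                f"{param}={candidates[a]:g}", stage.per_depth_rates[a],
                f"{param}={candidates[b]:g}", stage.per_depth_rates[b],
                depths=reference.depths,
            )
            if depth_cmp.winner == f"{param}={candidates[b]:g}":
                chosen_value = candidates[b]
        stages.append(stage)
        current = current.with_(**{param: chosen_value})
    return TuningOutcome(final_config=current, stages=tuple(stages),
                         depth_comparison=depth_cmp)
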