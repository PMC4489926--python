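"""Sticky-site grid, run batches, and knotting statistics.

The adhesive sites are placed on a regular grid: with chain length N and
grid spacing s, the arm lengths ``l_x`` (terminus A to site X) and ``l_y``
(terminus Omega to site Y) take values in multiples of s.  Placements are
canonicalized under chain-reversal symmetry (``l_x <= l_y``), coincident
sites are excluded, and the sticky loop X..Y must contain at least one
grid spacing of beads.  For N = 500, s = 50 this yields the 20
non-redundant placements of the study design.

The central observable is the relative knotting probability

    RKP = P_K(l_x, l_y) / P_K0

where ``P_K`` is the fraction of knotted final configurations over all
non-censored runs of the chain with both sticky pairs, and ``P_K0`` the
same fraction for a reference chain with adhesive termini only.  FCSL and
FTRSL are, among knotted configurations, the fractions with a closed
sticky loop and with a topologically *relevant* closed sticky loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .engine import bond_minimum, run_until_circularization
from .io import RunRecord, ledger_append, ledger_load
from .params import ModelParams, RunProtocol, config_hash
from .state import RunOutcome
from .topology import classify_polygon, close_chain, loop_relevance, KnotType

__all__ = [
    "SitePlacement",
    "ExperimentSummary",
    "CampaignResult",
    "enumerate_grid",
    "run_batch",
    "run_campaign",
    "rkp",
    "fcsl",
    "ftrsl",
    "knot_spectrum",
    "summarize",
    "bond_correlation_profile",
    "persistence_length",
    "measure_persistence_length",
]


@dataclass(frozen=True)
class SitePlacement:
    """Arm lengths of one sticky-site placement on an N-bead chain.

    ``l_x`` beads lie strictly between terminus A and site X, ``l_y``
    between terminus Omega and site Y; the sticky loop X..Y then contains
    ``N - l_x - l_y`` beads (inclusive of X and Y).
    """

    l_x: int
    l_y: int
    n_beads: int

    def __post_init__(self) -> None:
        if not (0 < self.l_x <= self.l_y):
            raise ValueError("require 0 < l_x <= l_y (canonical order)")
        if self.loop_length < 2:
            raise ValueError("sites must be distinct with X strictly before Y")

    @property
    def loop_length(self) -> int:
        return self.n_beads - self.l_x - self.l_y

    @property
    def x_index(self) -> int:
        return self.l_x

    @property
    def y_index(self) -> int:
        return self.n_beads - 1 - self.l_y

    @property
    def separation(self) -> int:
        """Sequence separation of the internal sticky beads."""
        return self.y_index - self.x_index

    @property
    def tag(self) -> str:
        return f"lx{self.l_x}-ly{self.l_y}"

    def internal_pair(self) -> Tuple[int, int]:
        return (self.x_index, self.y_index)


def enumerate_grid(n_beads: int, spacing: int) -> List[SitePlacement]:
    """All non-redundant sticky-site placements on the grid.

    Arm lengths run over multiples of ``spacing``; placements are
    deduplicated under chain reversal (``l_x <= l_y``), coincident sites
    are excluded, and the loop must be at least one spacing long.
    """
    if spacing <= 0 or spacing >= n_beads / 2:
        raise ValueError("spacing must be positive and < n_beads/2")
    out = []
    for l_x in range(spacing, n_beads, spacing):
        for l_y in range(l_x, n_beads, spacing):
            if n_beads - l_x - l_y >= spacing:
                out.append(SitePlacement(l_x, l_y, n_beads))
    return out


# ---------------------------------------------------------------------------
# run batches
# ---------------------------------------------------------------------------

def run_batch(
    placement: Optional[SitePlacement],
    params: ModelParams,
    protocol: RunProtocol,
    n_runs: int,
    seed_base: int,
    *,
    ledger_path=None,
    classify: bool = True,
    keep_outcomes: bool = False,
) -> List[RunRecord]:
    """Run ``n_runs`` independent chains and return their ledger records.

    ``placement=None`` runs the *reference* chain (adhesive termini only),
    which defines the denominator P_K0 of the RKP.  Run *i* uses seed
    ``seed_base + i``; with a ``ledger_path`` the batch is resumable —
    records already present are not recomputed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    internal = placement.internal_pair() if placement is not None else None
    p = params.replace(
        sticky_terminal_pair=(0, params.n_beads - 1),
        sticky_internal_pair=internal,
    )
    chash = config_hash(p, protocol)
    tag = placement.tag if placement is not None else "reference"

    done_ids = set()
    records: List[RunRecord] = []
    if ledger_path is not None:
        try:
            existing = ledger_load(ledger_path)
        except FileNotFoundError:
            existing = []
        for r in existing:
            if r.config_hash == chash and r.placement == tag:
                done_ids.add(r.run_id)
                records.append(r)

    for i in range(n_runs):
        seed = seed_base + i
        run_id = f"{tag}-{seed}"
        if run_id in done_ids:
            continue
        proto_i = protocol.replace(seed=seed)
        outcome = run_until_circularization(p, proto_i)
        rec = _record_from_outcome(
            run_id, chash, tag, placement, p, proto_i, outcome, classify
        )
        if keep_outcomes:
            rec.outcome = outcome
        records.append(rec)
        if ledger_path is not None:
            ledger_append(ledger_path, [rec])
    return records


def _record_from_outcome(
    run_id: str,
    chash: str,
    tag: str,
    placement: Optional[SitePlacement],
    params: ModelParams,
    protocol: RunProtocol,
    outcome: RunOutcome,
    classify: bool,
) -> RunRecord:
    rec = RunRecord(
        run_id=run_id,
        config_hash=chash,
        seed=protocol.seed,
        placement=tag,
        circularized=outcome.circularized,
        censored=outcome.censored,
        steps=outcome.steps_elapsed,
        loop_closed=(
            bool(outcome.internal_loop_closed_at_end)
            if placement is not None and outcome.circularized
            else None
        ),
    )
    if outcome.circularized and classify:
        poly = close_chain(outcome, params)
        # topology seeds derive from the run seed: fully reproducible
        knot = classify_polygon(poly, seed=protocol.seed)
        rec.knot_label = knot.label
        rec.det_minus1 = knot.det_minus1
        rec.det_minus2 = knot.det_minus2
        if knot.label != "0_1" and rec.loop_closed:
            rel = loop_relevance(poly, knot, seed=protocol.seed)
            rec.relevant = rel.relevant
    return rec


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _counts(records: Sequence[RunRecord]) -> Tuple[int, int, int]:
    """(knotted, non-censored, censored) counts of a batch."""
    knotted = sum(
        1 for r in records if r.circularized and r.knot_label not in (None, "0_1")
    )
    ok = sum(1 for r in records if r.circularized)
    censored = sum(1 for r in records if r.censored)
    return knotted, ok, censored


@dataclass(frozen=True)
class Ratio:
    """A ratio estimate with a (log-scale Katz) confidence interval."""

    value: float
    ci_low: float
    ci_high: float


def rkp(
    knotted: int,
    total: int,
    ref_knotted: int,
    ref_total: int,
    alpha: float = 0.05,
) -> Ratio:
    """Relative knotting probability with a Katz log-ratio interval.

    ``P_K / P_K0`` where each probability is knotted over non-censored
    runs.  A zero reference knot count leaves the RKP undefined and
    raises.  A zero numerator yields a point estimate of 0 with an upper
    bound computed with a 0.5 continuity correction.
    """
    if ref_knotted <= 0:
        raise ValueError("RKP undefined: reference batch has zero knots")
    if total <= 0 or ref_total <= 0:
        raise ValueError("RKP needs non-censored runs on both sides")
    p1 = knotted / total
    p0 = ref_knotted / ref_total
    value = p1 / p0
    z = sps.norm.ppf(1 - alpha / 2)
    k1 = knotted if knotted > 0 else 0.5
    se = math.sqrt(
        max(1.0 / k1 - 1.0 / total + 1.0 / ref_knotted - 1.0 / ref_total, 0.0)
    )
    center = (k1 / total) / p0
    lo = 0.0 if knotted == 0 else center * math.exp(-z * se)
    hi = center * math.exp(z * se)
    return Ratio(value, lo, hi)


def _knotted_records(records: Sequence[RunRecord]) -> List[RunRecord]:
    return [
        r for r in records if r.circularized and r.knot_label not in (None, "0_1")
    ]


def fcsl(records: Sequence[RunRecord]) -> float:
    """Fraction of knotted chains whose sticky loop is closed."""
    knotted = _knotted_records(records)
    if not knotted:
        raise ValueError("FCSL undefined: no knotted runs")
    return sum(1 for r in knotted if r.loop_closed) / len(knotted)


def ftrsl(records: Sequence[RunRecord]) -> float:
    """Fraction of knotted chains with a closed, topologically relevant loop."""
    knotted = _knotted_records(records)
    if not knotted:
        raise ValueError("FTRSL undefined: no knotted runs")
    return sum(1 for r in knotted if r.loop_closed and r.relevant) / len(knotted)


def knot_spectrum(
    records: Sequence[RunRecord], as_fractions: bool = True
) -> Dict[str, float]:
    """Knot-type abundances over the knotted runs (fractions sum to 1)."""
    knotted = _knotted_records(records)
    if not knotted:
        raise ValueError("knot spectrum undefined: no knotted runs")
    counts: Dict[str, float] = {}
    for r in knotted:
        counts[r.knot_label] = counts.get(r.knot_label, 0) + 1
    if as_fractions:
        tot = sum(counts.values())
        counts = {k: v / tot for k, v in counts.items()}
    return counts


@dataclass
class ExperimentSummary:
    """Per-placement aggregates of one batch (plus its reference)."""

    placement: Optional[SitePlacement]
    n_runs: int
    n_censored: int
    n_knotted: int
    p_k: float
    p_k_ci: Tuple[float, float]
    rkp: Optional[Ratio] = None
    fcsl: Optional[float] = None
    ftrsl: Optional[float] = None
    spectrum: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "placement": self.placement.tag if self.placement else "reference",
            "l_x": self.placement.l_x if self.placement else None,
            "l_y": self.placement.l_y if self.placement else None,
            "n_runs": self.n_runs,
            "n_censored": self.n_censored,
            "n_knotted": self.n_knotted,
            "p_k": self.p_k,
            "p_k_ci_low": self.p_k_ci[0],
            "p_k_ci_high": self.p_k_ci[1],
            "rkp": self.rkp.value if self.rkp else None,
            "rkp_ci_low": self.rkp.ci_low if self.rkp else None,
            "rkp_ci_high": self.rkp.ci_high if self.rkp else None,
            "fcsl": self.fcsl,
            "ftrsl": self.ftrsl,
        }
        for label, frac in sorted(self.spectrum.items()):
            d[f"spectrum_{label}"] = frac
        return d


def summarize(
    records: Sequence[RunRecord],
    placement: Optional[SitePlacement] = None,
    reference: Optional[Sequence[RunRecord]] = None,
) -> ExperimentSummary:
    """Aggregate a batch into probabilities, fractions and the spectrum.

    Censored runs are excluded from both numerator and denominator of all
    probabilities; their count is reported.  The single-proportion interval
    is Wilson's.
    """
    knotted, ok, censored = _counts(records)
    if ok == 0:
        raise ValueError("no non-censored runs to summarize")
    p_k = knotted / ok
    lo, hi = proportion_confint(knotted, ok, alpha=0.05, method="wilson")
    summary = ExperimentSummary(
        placement=placement,
        n_runs=len(records),
        n_censored=censored,
        n_knotted=knotted,
        p_k=p_k,
        p_k_ci=(float(lo), float(hi)),
    )
    if reference is not None:
        ref_knotted, ref_ok, _ = _counts(reference)
        # a knot-free reference leaves the RKP undefined (rkp() raises);
        # record the absence rather than aborting a whole campaign
        if ref_knotted > 0:
            summary.rkp = rkp(knotted, ok, ref_knotted, ref_ok)
    if knotted > 0:
        summary.spectrum = knot_spectrum(records)
        if any(r.loop_closed is not None for r in records):
            summary.fcsl = fcsl(records)
            summary.ftrsl = ftrsl(records)
    return summary


# ---------------------------------------------------------------------------
# campaigns
# ---------------------------------------------------------------------------

@dataclass
class CampaignResult:
    """Everything a grid campaign produced: records and summaries."""

    reference: List[RunRecord]
    batches: Dict[SitePlacement, List[RunRecord]]
    reference_summary: ExperimentSummary
    summaries: Dict[SitePlacement, ExperimentSummary]

    def table(self) -> pd.DataFrame:
        """Tidy per-placement table (l_x, l_y, metrics, intervals)."""
        rows = [self.reference_summary.to_dict()]
        rows += [s.to_dict() for s in self.summaries.values()]
        return pd.DataFrame(rows)


def run_campaign(
    *,
    n_beads: int,
    spacing: int,
    regime: str,
    runs_per_placement: int,
    reference_runs: int,
    protocol: RunProtocol,
    seed: int,
    ledger_path=None,
) -> CampaignResult:
    """Run the full placement grid plus the shared reference batch.

    The reference chain (sticky termini only) is simulated once per
    campaign and its knotted fraction is the common RKP denominator for
    every placement, since the denominator does not depend on the
    placement.  Run seeds are disjoint blocks derived from ``seed``.
    """
    params = ModelParams.chain(n_beads, regime=regime)
    grid = enumerate_grid(n_beads, spacing)
    block = 1_000_000
    reference = run_batch(
        None, params, protocol, reference_runs, seed, ledger_path=ledger_path
    )
    ref_summary = summarize(reference)
    batches: Dict[SitePlacement, List[RunRecord]] = {}
    summaries: Dict[SitePlacement, ExperimentSummary] = {}
    for b, placement in enumerate(grid, start=1):
        recs = run_batch(
            placement,
            params,
            protocol,
            runs_per_placement,
            seed + b * block,
            ledger_path=ledger_path,
        )
        batches[placement] = recs
        summaries[placement] = summarize(recs, placement=placement, reference=reference)
    return CampaignResult(reference, batches, ref_summary, summaries)


# ---------------------------------------------------------------------------
# persistence length
# ---------------------------------------------------------------------------

def bond_correlation_profile(
    params: ModelParams,
    protocol: RunProtocol,
    n_steps: int,
    *,
    equilibration_steps: int = 0,
    sample_interval: int = 1000,
    max_separation: Optional[int] = None,
) -> np.ndarray:
    """Mean bond-direction correlation <cos theta(s)> of an open chain.

    Runs an open chain (no adhesive interactions should be present in
    ``params``) and averages the scalar product of unit bond vectors a
    sequence separation ``s`` apart, over bonds and sampled frames.
    Element ``s`` of the returned array is the correlation at separation
    ``s`` (element 0 is 1 by construction).
    """
    if params.sticky_terminal_pair is not None or params.sticky_internal_pair is not None:
        raise ValueError("persistence length requires a chain without sticky pairs")
    from . import _kernels
    from .engine import (  # reuse engine plumbing
        _kernel_args,
        _noise_generator,
        _scratch,
        initial_conformation,
    )

    rng = np.random.default_rng(protocol.seed)
    noise_rng = _noise_generator(protocol.seed)
    state = initial_conformation(params, protocol, rng)
    n = params.n_beads
    n_bonds = n - 1
    smax = max_separation if max_separation is not None else n_bonds - 1
    acc = np.zeros(smax + 1)
    cnt = np.zeros(smax + 1)
    bonded = np.zeros(2, dtype=np.int8)
    pairs_i, pairs_j, pos_ref = _scratch(params)
    args = _kernel_args(params, protocol)

    total = equilibration_steps + n_steps
    done = 0
    noise_buf = np.zeros((sample_interval, n, 3), dtype=np.float32)
    while done < total:
        chunk = min(sample_interval, total - done)
        noise = noise_buf[:chunk]
        if protocol.gamma > 0:
            noise_rng.standard_normal(out=noise, dtype=np.float32)
        status, steps, _ = _kernels.run_chunk(
            state.positions, state.velocities, noise, *args,
            bonded, protocol.capture_distance**2, pairs_i, pairs_j, pos_ref,
        )
        if status == _kernels.STATUS_FENE_DIV:
            raise FloatingPointError("FENE divergence during persistence run")
        done += steps
        if done > equilibration_steps:
            b = state.positions[1:] - state.positions[:-1]
            u = b / np.linalg.norm(b, axis=1, keepdims=True)
            for s in range(smax + 1):
                prods = (u[: n_bonds - s] * u[s:]).sum(axis=1)
                acc[s] += prods.sum()
                cnt[s] += prods.size
    return acc / cnt


def persistence_length(
    correlations: np.ndarray,
    bond_length: float,
    *,
    noise_floor: float = 0.05,
    min_points: int = 2,
) -> float:
    """Persistence length from an exponential fit of <cos theta(s)>.

    Fits ``<cos theta(s)> = exp(-s * b / l_p)`` by weighted least squares
    on the log, over separations where the correlation exceeds
    ``noise_floor`` (below which the estimate is statistics-dominated).
    Returns ``l_p`` in units of sigma.  A profile that does not decay
    (rigid rod) raises, as the estimate is unbounded.
    """
    c = np.asarray(correlations, dtype=float)
    usable = c > noise_floor
    # use the contiguous leading stretch above the floor
    end = len(c)
    for s in range(1, len(c)):
        if not usable[s]:
            end = s
            break
    s_vals = np.arange(1, end)
    if len(s_vals) < min_points:
        raise ValueError("correlation decays too fast for a stable fit")
    y = np.log(c[1:end])
    if c[end - 1] > 0.9:
        raise ValueError("correlation does not decay: rigid-rod-like input")
    # weights ~ 1/var(log c) ~ c^2: de-emphasize the noisy tail
    w = c[1:end] ** 2
    slope = np.sum(w * s_vals * y) / np.sum(w * s_vals**2)
    if slope >= 0:
        raise ValueError("non-decaying correlation profile")
    return float(-bond_length / slope)


def measure_persistence_length(
    params: ModelParams,
    protocol: RunProtocol,
    n_steps: int,
    *,
    equilibration_steps: int = 0,
    sample_interval: int = 1000,
    max_separation: Optional[int] = None,
) -> float:
    """Convenience wrapper: simulate an open chain and fit l_p."""
    corr = bond_correlation_profile(
        params,
        protocol,
        n_steps,
        equilibration_steps=equilibration_steps,
        sample_interval=sample_interval,
        max_separation=max_separation,
    )
    return persistence_length(corr, bond_minimum(params))
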