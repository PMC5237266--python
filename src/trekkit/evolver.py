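"""In-silico neutral evolution of a sequence under a k-mer rate database.

Substitutions are sampled in batches, weighted by the current per-position
rate constants (time-homogeneous weighted sampling; the trajectory is
tracked in substitution counts, not time).  After each batch only the
positions within +/-3 nt of an applied substitution have their rates
refreshed, since the context window is 7 nt.  The run stops when the G+C
content stops drifting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, decode
from .datamodel import TrekDatabase
from .mapper import rates_for_codes

#: trajectory row: (total substitutions, G+C fraction, A/C/G/T fractions)
TrajectoryEntry = tuple[int, float, tuple[float, float, float, float]]


@dataclass
class EvolverState:
    codes: np.ndarray                      # uint8, mutable in place
    rates: np.ndarray                      # (L, 4) byr^-1, self-target = 0
    db: TrekDatabase
    rng: np.random.Generator
    seed: int
    total_substitutions: int = 0
    trajectory: list[TrajectoryEntry] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return decode(self.codes)

    def composition(self) -> np.ndarray:
        """A/C/G/T fractions of the current sequence."""
        return np.bincount(self.codes, minlength=4)[:4] / len(self.codes)

    def gc_content(self) -> float:
        comp = self.composition()
        return float(comp[1] + comp[2])

    def record(self) -> None:
        comp = self.composition()
        self.trajectory.append(
            (self.total_substitutions, float(comp[1] + comp[2]), tuple(comp))
        )

    def check_rates(self) -> bool:
        """True when the lazily maintained rates equal a full recomputation."""
        return bool(np.allclose(self.rates, rates_for_codes(self.db, self.codes)))


def init_sequence(length: int, composition, seed: int,
                  db: TrekDatabase) -> EvolverState:
    """I.i.d. random start sequence with the stated A/C/G/T composition."""
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be 4 fractions summing to 1")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=comp).astype(np.uint8)
    state = EvolverState(codes=codes, rates=rates_for_codes(db, codes),
                         db=db, rng=rng, seed=seed)
    state.record()
    return state


def _refresh(state: EvolverState, changed: np.ndarray) -> None:
    """Recompute rates for all positions within +/-3 nt of any change."""
    L = len(state.codes)
    affected = np.unique((changed[:, None] + np.arange(-3, 4)[None, :]).ravel())
    affected = affected[(affected >= 0) & (affected < L)]
    lo, hi = int(affected.min()), int(affected.max())
    if hi - lo < 2 * len(affected):  # contiguous-ish span: one vector call
        span_lo, span_hi = max(lo - 3, 0), min(hi + 3, L - 1)
        sub = rates_for_codes(state.db, state.codes[span_lo : span_hi + 1])
        state.rates[affected] = sub[affected - span_lo]
    else:
        full = rates_for_codes(state.db, state.codes)
        state.rates[affected] = full[affected]


def evolve_step(state: EvolverState, batch: int = 5000) -> EvolverState:
    """Apply one batch of rate-weighted substitutions, then refresh locally.

    Within a batch, positions are sampled without replacement proportionally
    to their total rate (Gumbel top-k), so no position is hit twice before
    the rate update; ``batch=1`` recovers the exact sequential chain.
    """
    total = state.rates.sum(axis=1)
    positive = int(np.count_nonzero(total))
    if positive == 0:
        raise RuntimeError("absorbed state: all substitution rates are zero")
    if batch > positive:
        raise ValueError(f"batch {batch} exceeds {positive} mutable positions")
    with np.errstate(divide="ignore"):
        keys = np.log(total) + state.rng.gumbel(size=len(total))
    if batch < len(total):
        pos = np.argpartition(keys, -batch)[-batch:]
    else:
        pos = np.arange(len(total))
    row = state.rates[pos]
    cum = np.cumsum(row, axis=1)
    u = state.rng.random(len(pos)) * cum[:, -1]
    targets = (u[:, None] >= cum).sum(axis=1).astype(np.uint8)
    state.codes[pos] = targets
    state.total_substitutions += len(pos)
    _refresh(state, pos)
    state.record()
    return state


@dataclass
class EquilibriumResult:
    trajectory: list[TrajectoryEntry]
    converged: bool
    final_composition: np.ndarray
    final_gc: float


def run_to_equilibrium(state: EvolverState, batch: int = 5000,
                       window: float = 2.0, tolerance: float | None = None,
                       max_substitutions: int | None = None) -> EquilibriumResult:
    """Evolve until the G+C content is flat across a trailing window.

    ``window`` is in substitutions per site (default 2); convergence is
    declared when the G+C drift across that window — the difference of its
    first- and second-half mean G+C — falls below ``tolerance``.  The
    default tolerance, max(0.05 pp, 3*sqrt(0.25/L)), floors the nominal
    0.05-percentage-point criterion at the binomial Monte-Carlo noise of
    the sequence length, so short sequences can terminate.  A cap of
    ``max_substitutions`` (default 20 per site) returns with a warning.
    """
    L = len(state.codes)
    if max_substitutions is None:
        max_substitutions = 20 * L
    if tolerance is None:
        tolerance = max(0.0005, 3.0 * np.sqrt(0.25 / L))
    window_subs = int(window * L)
    converged = False
    while state.total_substitutions < max_substitutions:
        evolve_step(state, batch=batch)
        n_now = state.total_substitutions
        if n_now < window_subs:
            continue
        tail = [gc for subs, gc, _ in state.trajectory if subs >= n_now - window_subs]
        half = len(tail) // 2
        if half >= 2 and abs(np.mean(tail[half:]) - np.mean(tail[:half])) < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn("equilibrium not reached before the substitution cap")
    comp = state.composition()
    return EquilibriumResult(trajectory=state.trajectory, converged=converged,
                             final_composition=comp,
                             final_gc=float(comp[1] + comp[2]))
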