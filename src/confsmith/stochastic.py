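"""Stochastic conformer sampling.

Random low-energy conformers are generated iteratively by the
distance-geometry unit until a sample cap is reached, the time budget is
exhausted, or the generation of new unique conformers has ceased
(convergence).  Every generated conformer must lie within the energy
window above the lowest energy encountered so far; convergence is decided
by energy-based duplicate removal at a fixed cycle period.  Duplicate
removal by energy alone can in principle merge distinct isoenergetic
conformers - the final geometric de-duplication happens later during
output ensemble compilation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import distgeom as dg
from . import forcefield as ff
from .molprep import MoleculeGraph

__all__ = ["StochasticSettings", "SamplingFailure", "sample", "remove_energy_duplicates"]

DUPLICATE_ENERGY_WINDOW = 0.01  # kcal/mol


class SamplingFailure(RuntimeError):
    """Not a single conformer could be generated."""


@dataclass
class StochasticSettings:
    """Knobs of the sampling loop."""

    max_samples: int = 2000
    convergence_period: int = 100   # cycles between convergence checks
    duplicate_window: float = DUPLICATE_ENERGY_WINDOW
    energy_window: float = 20.0     # kcal/mol above the running minimum
    time_budget: float = 0.0        # seconds; 0 = unlimited
    dg: dg.DGSettings = None

    def __post_init__(self):
        if self.dg is None:
            self.dg = dg.DGSettings(
                init_factor=0.5,
                stop_criterion="energy_delta",
                stop_threshold=0.001,
            )
        if min(self.max_samples, self.convergence_period) <= 0:
            raise ValueError("sample cap and period must be positive")
        if self.time_budget < 0:
            raise ValueError("time budget must be >= 0")


def remove_energy_duplicates(
    ensemble: list[dg.Conformer],
    window: float = DUPLICATE_ENERGY_WINDOW,
) -> list[dg.Conformer]:
    """Keep one member per cluster of energy-near-duplicates.

    Sorted ascending by energy (stable w.r.t. insertion order); a member
    is dropped iff its energy is within ``window`` of an already kept
    member, so the lowest-energy member of every pairwise-close cluster
    survives.
    """
    order = sorted(range(len(ensemble)), key=lambda k: (ensemble[k].energy, k))
    kept: list[dg.Conformer] = []
    for k in order:
        e = ensemble[k].energy
        if any(abs(e - c.energy) <= window for c in kept):
            continue
        kept.append(ensemble[k])
    return kept


def sample(
    mg: MoleculeGraph,
    param: ff.ForceFieldParametrization,
    settings: Optional[StochasticSettings] = None,
    rng: Optional[np.random.Generator] = None,
    generator: Optional[dg.RandomConformerGenerator] = None,
    deadline: Optional[float] = None,
) -> list[dg.Conformer]:
    """Run the stochastic sampling loop; returns the candidate ensemble.

    One cycle equals one random-conformer generation attempt (successful
    or not).  ``deadline`` (``time.monotonic`` value) allows a caller to
    impose an external per-molecule budget on top of
    ``settings.time_budget``.
    """
    settings = settings or StochasticSettings()
    rng = rng if rng is not None else np.random.default_rng()
    gen = generator or dg.RandomConformerGenerator(mg, param, settings.dg)

    t0 = time.monotonic()
    limit = t0 + settings.time_budget if settings.time_budget > 0 else None
    if deadline is not None:
        limit = deadline if limit is None else min(limit, deadline)

    working: list[dg.Conformer] = []
    e_min = np.inf
    size_at_last_check = 0
    cycles = 0
    while cycles < settings.max_samples:
        if limit is not None and time.monotonic() > limit:
            break
        cycles += 1
        try:
            conf = gen.generate(rng)
        except dg.GenerationError:
            conf = None
        if conf is not None:
            e_min = min(e_min, conf.energy)
            if conf.energy <= e_min + settings.energy_window:
                working.append(conf)
        if cycles % settings.convergence_period == 0:
            working = remove_energy_duplicates(working, settings.duplicate_window)
            if len(working) <= size_at_last_check and working:
                break
            size_at_last_check = len(working)

    working = remove_energy_duplicates(working, settings.duplicate_window)
    working = [c for c in working if c.energy <= e_min + settings.energy_window]
    if not working:
        raise SamplingFailure(
            f"stochastic sampling produced no conformer for {mg.name!r}"
        )
    return working
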