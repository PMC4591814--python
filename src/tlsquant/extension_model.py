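"""Generative model of processive primer extension over a lesion.

Each primer molecule starts at terminus N0. During one polymerase
*engagement* the enzyme attempts insertions at consecutive positions
N(j+1), N(j+2), ... from the current terminus j; each attempt succeeds
with the position's continuation probability s_i and the engagement ends
(the enzyme dissociates) at the first failure or at full length NK.
Dissociation is memoryless: a later engagement resumes from the current
terminus with the same per-position probabilities. The number of
engagements per molecule over an incubation of t minutes is
Poisson(lambda*t), with lambda the engagement rate. In the single-hit
limit (at most one engagement per molecule) the assay's insertion
statistic is an unbiased estimator of s_i.

The continuation probabilities come from an :class:`ExtensionProfile`:
``e_correct[i]`` applies when the Watson-Crick dNTP for position Ni is in
the reaction, ``e_mis[i]`` otherwise (single-dNTP reactions), and
positions at or beyond a nick are further multiplied by the profile's
strand-displacement factor.

:func:`expected_length_distribution` gives the exact product-length
distribution (an analytic oracle for the Monte-Carlo simulator);
:func:`simulate_lanes` adds finite molecule counts and densitometry noise
(multiplicative log-normal per band plus additive background, clamped at
zero) to produce synthetic :class:`~tlsquant.quantify.Lane` tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .quantify import Lane
from .substrates import Substrate, position_map

ALL_DNTPS = frozenset({"dATP", "dCTP", "dGTP", "dTTP"})

#: Poisson mixture truncated when the remaining tail mass drops below this.
POISSON_TAIL_TOL = 1e-12


@dataclass
class ExtensionProfile:
    """Per-position continuation probabilities of one enzyme on one substrate.

    ``e_correct``/``e_mis`` have length K (the substrate's extendable
    positions); ``displacement_factor`` in [0,1] multiplies continuation at
    positions at/beyond a nick (1 = unimpeded strand displacement).
    """

    label: str
    e_correct: np.ndarray
    e_mis: np.ndarray
    displacement_factor: float = 1.0

    def __post_init__(self) -> None:
        self.e_correct = np.asarray(self.e_correct, dtype=float)
        self.e_mis = np.asarray(self.e_mis, dtype=float)
        for name, arr in (("e_correct", self.e_correct), ("e_mis", self.e_mis)):
            if arr.ndim != 1:
                raise ConfigurationError(f"{name} must be a 1-D vector")
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigurationError(f"{name} entries must lie in [0, 1]")
        if self.e_correct.size != self.e_mis.size:
            raise ConfigurationError("e_correct and e_mis must have equal length")
        if not 0 <= self.displacement_factor <= 1:
            raise ConfigurationError("displacement_factor must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.e_correct.size


@dataclass
class ReactionConditions:
    """Reaction/lane design for the simulator.

    times are incubation durations in minutes (the assay uses 2, 4 and 6);
    ``engagement_rate`` is the expected polymerase engagements per molecule
    per minute (lambda); ``replicates`` is the number of independent lanes
    per time point; ``noise_sigma_mult`` the log-normal sigma of the
    multiplicative band noise and ``background`` the mean additive
    background per band. ``single_hit`` forces exactly one engagement per
    molecule (the conditional M=1 regime) instead of Poisson draws.
    """

    seed: int
    dntps: FrozenSet[str] = ALL_DNTPS
    times: Sequence[float] = (2.0, 4.0, 6.0)
    engagement_rate: float = 0.05
    molecules: int = 20_000
    noise_sigma_mult: float = 0.05
    background: float = 0.0
    replicates: int = 2
    single_hit: bool = False

    def __post_init__(self) -> None:
        self.dntps = frozenset(self.dntps)
        if not self.dntps <= ALL_DNTPS:
            raise ConfigurationError(f"unknown dNTPs: {sorted(self.dntps - ALL_DNTPS)}")
        if self.molecules < 1:
            raise ConfigurationError("molecules must be >= 1")
        if not self.times or any(t <= 0 for t in self.times):
            raise ConfigurationError("times must be non-empty and positive")
        if self.engagement_rate < 0:
            raise ConfigurationError("engagement_rate must be >= 0")
        if self.noise_sigma_mult < 0 or self.background < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")


def effective_continuation(
    profile: ExtensionProfile,
    substrate: Substrate,
    dntps: Iterable[str] = ALL_DNTPS,
) -> np.ndarray:
    """Continuation vector s for one reaction: e_correct where the correct
    dNTP is present, e_mis otherwise, times the displacement factor at
    positions at/beyond the nick."""
    if profile.k != substrate.k:
        raise ConfigurationError(
            f"profile length {profile.k} != substrate K {substrate.k}"
        )
    dntps = frozenset(dntps)
    s = np.empty(substrate.k)
    for info in position_map(substrate):
        i = info.n - 1
        s[i] = profile.e_correct[i] if info.dntp in dntps else profile.e_mis[i]
        if info.at_nick:
            s[i] *= profile.displacement_factor
    return s


def _apply_engagement(p: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Terminus distribution after one engagement from distribution ``p``."""
    k = s.size
    new = np.zeros(k + 1)
    new[k] += p[k]
    for j in range(k):
        mass = p[j]
        if mass == 0.0:
            continue
        for i in range(j + 1, k + 1):
            new[i - 1] += mass * (1.0 - s[i - 1])
            mass *= s[i - 1]
        new[k] += mass
    return new


def expected_length_distribution(
    s: Sequence[float],
    mean_engagements: float,
    *,
    n_engagements: Optional[int] = None,
    tail_tol: float = POISSON_TAIL_TOL,
) -> np.ndarray:
    """Exact product-length distribution over N0..NK.

    ``mean_engagements`` is lambda*t of the Poisson engagement count; when
    ``n_engagements`` is given the distribution is conditioned on exactly
    that many engagements instead. The Poisson mixture is truncated once
    the remaining tail mass is below ``tail_tol`` and renormalised; the
    result sums to 1 within 1e-12.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or np.any((s < 0) | (s > 1)):
        raise ConfigurationError("continuation vector entries must lie in [0, 1]")
    if mean_engagements < 0:
        raise ConfigurationError("mean_engagements must be >= 0")

    p = np.zeros(s.size + 1)
    p[0] = 1.0
    if n_engagements is not None:
        for _ in range(int(n_engagements)):
            p = _apply_engagement(p, s)
        return p

    lam = float(mean_engagements)
    weight = math.exp(-lam)  # Poisson pmf at m = 0
    result = weight * p
    covered = weight
    m = 0
    while 1.0 - covered > tail_tol:
        m += 1
        p = _apply_engagement(p, s)
        weight *= lam / m
        result += weight * p
        covered += weight
    return result / result.sum()


def simulate_lanes(
    profile: ExtensionProfile,
    substrate: Substrate,
    conditions: ReactionConditions,
) -> list[Lane]:
    """Monte-Carlo lanes for every time x replicate of ``conditions``.

    Per molecule the engagement count is Poisson(lambda*t) (or exactly 1
    under ``single_hit``); terminus counts are tallied at unit amplitude
    per molecule, then each band is multiplied by lognormal(0, sigma) noise
    and incremented by |Normal(background, background/3)|, clamped at 0.
    Bit-for-bit reproducible given the conditions seed.
    """
    rng = np.random.default_rng(conditions.seed)
    s = effective_continuation(profile, substrate, conditions.dntps)
    k = substrate.k
    lanes: list[Lane] = []
    for t in conditions.times:
        for rep in range(1, conditions.replicates + 1):
            if conditions.single_hit:
                engagements = np.ones(conditions.molecules, dtype=np.int64)
            else:
                engagements = rng.poisson(
                    conditions.engagement_rate * t, conditions.molecules
                )
            terminus = np.zeros(conditions.molecules, dtype=np.int64)
            for e in range(1, int(engagements.max(initial=0)) + 1):
                running = engagements >= e
                for pos in range(1, k + 1):
                    at = np.flatnonzero(running & (terminus == pos - 1))
                    if at.size == 0:
                        continue
                    advanced = rng.random(at.size) < s[pos - 1]
                    terminus[at[advanced]] = pos
                    running[at[~advanced]] = False
            counts = np.bincount(terminus, minlength=k + 1).astype(float)
            if conditions.noise_sigma_mult > 0:
                counts *= rng.lognormal(0.0, conditions.noise_sigma_mult, k + 1)
            if conditions.background > 0:
                counts += np.abs(
                    rng.normal(conditions.background, conditions.background / 3, k + 1)
                )
            np.maximum(counts, 0.0, out=counts)
            lanes.append(
                Lane(
                    lane_id=f"{profile.label}|{substrate.name}|t{t:g}|r{rep}",
                    enzyme=profile.label,
                    substrate_name=substrate.name,
                    time_min=float(t),
                    replicate=rep,
                    intensities=counts,
                )
            )
    return lanes


def example_profiles(
    k: int, lesion_n: int
) -> dict[str, dict[str, ExtensionProfile]]:
    """Two illustrative enzyme profiles on a K-position substrate.

    "WT-like" emulates a polymerase that bypasses a thymine glycol with
    moderate efficiency; "mutant-like" a primer-grip variant whose bypass
    is severely reduced while activity on undamaged DNA is nearly intact.
    Each carries a "damaged" and an "undamaged" continuation vector: the
    two differ only at the lesion position and the step immediately after
    it (insertion opposite the lesion and extension past it are the two
    steps a Tg impairs). All other positions share a processive baseline
    of 0.9; misinsertion is uniformly rare (0.005).
    """
    if not 1 <= lesion_n <= k - 1:
        raise ConfigurationError(f"lesion_n {lesion_n} outside 1..{k - 1}")
    # (insertion-at-lesion, extension-past-lesion) continuation values
    settings = {
        "WT-like": {"damaged": (0.296, 0.418), "undamaged": (0.729, 0.955)},
        "mutant-like": {"damaged": (0.130, 0.190), "undamaged": (0.675, 0.959)},
    }
    out: dict[str, dict[str, ExtensionProfile]] = {}
    for label, arms in settings.items():
        out[label] = {}
        for arm, (s_lesion, s_next) in arms.items():
            e = np.full(k, 0.9)
            e[lesion_n - 1] = s_lesion
            e[lesion_n] = s_next
            out[label][arm] = ExtensionProfile(
                label=label,
                e_correct=e,
                e_mis=np.full(k, 0.005),
            )
    return out
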