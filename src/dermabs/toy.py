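"""Penetration-probability thought experiment.

Absorption can be caricatured as a per-molecule penetration probability.
Two extremes bracket how relative absorption responds to dose:

* **Case 1** — only the molecule nearest the penetration barrier can
  penetrate (probability 1), all others 0. Expected relative absorption
  is then ``100/dose`` %: 100, 50, 10 and 1 % at doses of 1, 2, 10 and
  100 molecules. Absolute absorption is constant (one molecule), the
  log–log slope of absolute absorption on dose is 0.
* **Case 2** — every molecule penetrates with the same probability
  (0.1). Relative absorption is 10 % at every dose; absolute absorption
  is proportional to dose, log–log slope 1.

Real skin sits between the two; the calculator takes arbitrary
per-molecule probability vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MoleculeEnsemble",
    "case1_ensemble",
    "case2_ensemble",
    "expected_relative_absorption",
    "simulate_penetration",
    "CASE1_DOSES",
    "CASE2_DOSES",
]

#: dose series used in the two worked cases (molecules)
CASE1_DOSES = (1, 2, 10, 100)
CASE2_DOSES = (10, 20, 100, 1000)


@dataclass(frozen=True)
class MoleculeEnsemble:
    """Per-molecule penetration probabilities; length = dose in molecules."""

    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probabilities) < 1:
            raise ValueError("ensemble must contain at least one molecule")
        if any(not 0.0 <= p <= 1.0 for p in self.probabilities):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def dose(self) -> int:
        return len(self.probabilities)


def case1_ensemble(dose: int) -> MoleculeEnsemble:
    """Only the barrier-adjacent molecule penetrates (p = 1, rest 0)."""
    if dose < 1:
        raise ValueError(f"dose must be >= 1 molecule, got {dose}")
    return MoleculeEnsemble((1.0,) + (0.0,) * (dose - 1))


def case2_ensemble(dose: int, p: float = 0.1) -> MoleculeEnsemble:
    """Every molecule penetrates with the same probability ``p``."""
    if dose < 1:
        raise ValueError(f"dose must be >= 1 molecule, got {dose}")
    return MoleculeEnsemble((float(p),) * dose)


def expected_relative_absorption(ensemble: MoleculeEnsemble) -> float:
    """Expected relative absorption in %: 100 × Σpᵢ / N."""
    p = np.asarray(ensemble.probabilities)
    return float(100.0 * p.sum() / p.size)


def simulate_penetration(ensemble: MoleculeEnsemble, seed: int) -> int:
    """One stochastic realisation: independent Bernoulli draw per molecule.

    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(ensemble.probabilities)
    return int((rng.random(p.size) < p).sum())
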