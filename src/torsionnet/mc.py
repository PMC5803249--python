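"""Metropolis Monte Carlo over dihedral configurations.

Single-molecule, single-temperature sampler: each step perturbs one
uniformly chosen torsion by a uniform offset within ±proposal_width and
accepts with the Metropolis probability min(1, exp(−ΔE / k_B T)),
producing Boltzmann-distributed configurations under the active energy
model.  An optional low-energy classifier gates the chain: proposals
the gate calls high-energy are rejected without evaluating the energy
model at all (the cheap reject-on-high policy), so the gated chain
targets the model's Boltzmann distribution restricted to the gate's
low region.  A pass-through gate mode exists for bias measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["KB_KCAL_PER_MOL_K", "MCState", "MCTrajectory", "metropolis_step", "run_mc"]

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL_PER_MOL_K = 0.0019872041


@dataclass
class MCState:
    """Mutable state of one Metropolis chain."""

    angles: np.ndarray          # current configuration, degrees
    energy: float               # kcal/mol, consistent with the energy model
    temperature: float          # K
    rng: np.random.Generator
    step: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    n_gate_skipped: int = 0
    n_energy_calls: int = 0

    def __post_init__(self):
        self.angles = np.atleast_1d(np.asarray(self.angles, float)) % 360.0
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _model_energy(energy_model, angles) -> float:
    if callable(energy_model) and not hasattr(energy_model, "evaluate"):
        return float(energy_model(angles))
    return float(energy_model.evaluate(angles))


def _gate_is_low(gate, angles) -> bool:
    if hasattr(gate, "classify"):
        return bool(gate.classify(angles)[1])
    return bool(gate(angles))


def metropolis_step(state: MCState, proposal: np.ndarray, energy_model,
                    gate=None) -> bool:
    """Advance the chain by one proposal; returns True if accepted.

    With a gate present, a proposal classified high-energy is rejected
    before the energy model is called (gate-skip).  A non-finite
    proposal energy is treated as a rejection.
    """
    proposal = np.atleast_1d(np.asarray(proposal, float)) % 360.0
    if proposal.shape != state.angles.shape:
        raise ValueError("proposal dimension does not match the chain state")
    state.step += 1
    if gate is not None and not _gate_is_low(gate, proposal):
        state.n_gate_skipped += 1
        state.n_rejected += 1
        return False
    e_new = _model_energy(energy_model, proposal)
    state.n_energy_calls += 1
    if not math.isfinite(e_new):
        state.n_rejected += 1
        return False
    delta = e_new - state.energy
    if delta <= 0.0 or state.rng.random() < math.exp(
        -delta / (KB_KCAL_PER_MOL_K * state.temperature)
    ):
        state.angles = proposal
        state.energy = e_new
        state.n_accepted += 1
        return True
    state.n_rejected += 1
    return False


@dataclass
class MCTrajectory:
    """Recorded chain: per-step angles, energies and acceptance flags."""

    angles: np.ndarray        # (n_steps, n_d)
    energies: np.ndarray      # (n_steps,)
    accepted: np.ndarray      # (n_steps,) bool
    summary: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.angles,
            columns=[f"dihedral_{d}_deg" for d in range(self.angles.shape[1])],
        )
        df.insert(0, "step", np.arange(1, len(df) + 1))
        df["energy_kcal_mol"] = self.energies
        df["accepted"] = self.accepted.astype(int)
        return df

    def save(self, path):
        self.to_dataframe().to_csv(path, index=False)


def run_mc(initial_angles, energy_model, n_steps: int, temperature: float,
           proposal_width: float = 30.0, gate=None, seed: int = 0) -> MCTrajectory:
    """Run a Metropolis chain and record its trajectory.

    Proposals perturb one uniformly chosen dihedral by a uniform offset
    in ±``proposal_width`` degrees.  Fully reproducible from ``seed``.
    The summary reports acceptance and gate-skip rates, energy-model
    call count, and the final state.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    rng = np.random.default_rng(seed)
    angles0 = np.atleast_1d(np.asarray(initial_angles, float)) % 360.0
    state = MCState(
        angles=angles0,
        energy=_model_energy(energy_model, angles0),
        temperature=temperature,
        rng=rng,
    )
    n_d = angles0.shape[0]
    traj_angles = np.empty((n_steps, n_d))
    traj_energy = np.empty(n_steps)
    traj_accept = np.empty(n_steps, dtype=bool)
    for s in range(n_steps):
        which = int(rng.integers(n_d))
        offset = rng.uniform(-proposal_width, proposal_width)
        proposal = state.angles.copy()
        proposal[which] = (proposal[which] + offset) % 360.0
        traj_accept[s] = metropolis_step(state, proposal, energy_model, gate=gate)
        traj_angles[s] = state.angles
        traj_energy[s] = state.energy
    summary = {
        "n_steps": n_steps,
        "temperature_K": temperature,
        "proposal_width_deg": proposal_width,
        "seed": seed,
        "acceptance_rate": state.n_accepted / n_steps,
        "gate_skip_rate": state.n_gate_skipped / n_steps,
        "energy_model_calls": state.n_energy_calls,
        "final_energy_kcal_mol": state.energy,
        "final_angles_deg": state.angles.tolist(),
    }
    return MCTrajectory(traj_angles, traj_energy, traj_accept, summary)
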