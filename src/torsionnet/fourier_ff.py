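"""Uncorrelated (single-angle) dihedral force fields.

The classical intramolecular torsion energy is a sum of independent
one-angle terms.  Each term is either the standard four-term Fourier
series

    E(φ) = V1/2 (1 + cos(φ − φ1)) + V2/2 (1 − cos(2φ − φ2))
         + V3/2 (1 + cos(3φ − φ3)) + V4/2 (1 − cos(4φ − φ4))

(note the alternating signs) or a tabulated profile with periodic
interpolation.  Models are parameterized by scanning each torsion on an
equally spaced grid while all other torsions are held at a reference
configuration — the n_s·n_d-evaluation procedure whose blindness to
angle–angle correlations this package exists to quantify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "FourierDihedralModel",
    "TabulatedDihedralModel",
    "eval_fourier",
    "scan_parameterize",
    "OracleError",
]

# sign s_m of the cos term in V_m/2 (1 + s_m cos(mφ − φ_m)), m = 1..4
_SIGNS = np.array([1.0, -1.0, 1.0, -1.0])
_ORDERS = np.array([1.0, 2.0, 3.0, 4.0])


class OracleError(RuntimeError):
    """An external energy oracle failed on a scanned configuration."""


@dataclass
class FourierDihedralModel:
    """Per-dihedral four-term Fourier coefficients plus a global offset.

    amplitudes : (n_d, 4) array of V1..V4 in kcal/mol
    phases     : (n_d, 4) array of φ1..φ4 in degrees, canonical [0, 360)
    offset     : global energy offset, kcal/mol
    """

    amplitudes: np.ndarray
    phases: np.ndarray
    offset: float = 0.0

    def __post_init__(self):
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, float))
        self.phases = np.atleast_2d(np.asarray(self.phases, float)) % 360.0
        if self.amplitudes.shape != self.phases.shape or self.amplitudes.shape[1] != 4:
            raise ValueError("amplitudes and phases must both be (n_d, 4)")

    @property
    def n_dihedrals(self) -> int:
        return self.amplitudes.shape[0]

    def evaluate_batch(self, angles_deg: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(angles_deg, float))
        if a.shape[1] != self.n_dihedrals:
            raise ValueError(
                f"configuration has {a.shape[1]} angles, model has {self.n_dihedrals}"
            )
        phi = np.radians(a)[:, :, None] * _ORDERS[None, None, :]
        shift = np.radians(self.phases)[None, :, :]
        terms = 0.5 * self.amplitudes[None, :, :] * (
            1.0 + _SIGNS[None, None, :] * np.cos(phi - shift)
        )
        return terms.sum(axis=(1, 2)) + self.offset

    def evaluate(self, angles_deg) -> float:
        return float(self.evaluate_batch(np.atleast_2d(angles_deg))[0])

    def to_dict(self) -> dict:
        return {
            "kind": "fourier",
            "units": "kcal/mol, degrees",
            "amplitudes": self.amplitudes.tolist(),
            "phases": self.phases.tolist(),
            "offset": float(self.offset),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FourierDihedralModel":
        return cls(np.array(d["amplitudes"]), np.array(d["phases"]), d["offset"])


def eval_fourier(model: FourierDihedralModel, angles_deg) -> float:
    """Energy (kcal/mol) of a configuration under the Fourier dihedral model."""
    return model.evaluate(angles_deg)


@dataclass
class TabulatedDihedralModel:
    """Per-dihedral tabulated torsion profiles with periodic interpolation.

    grid_energies : (n_d, n_s) energies (kcal/mol) on the equally spaced
                    grid 0, 360/n_s, …, 360(n_s−1)/n_s degrees
    offset        : global energy offset, kcal/mol
    kind          : 'cubic' (periodic cubic spline, default) or 'linear'
    """

    grid_energies: np.ndarray
    offset: float = 0.0
    kind: str = "cubic"

    def __post_init__(self):
        self.grid_energies = np.atleast_2d(np.asarray(self.grid_energies, float))
        if self.grid_energies.shape[1] < 8:
            raise ValueError("need at least 8 grid samples per dihedral")
        if self.kind not in ("cubic", "linear"):
            raise ValueError(f"unknown interpolation kind {self.kind!r}")
        self._splines = None

    @property
    def n_dihedrals(self) -> int:
        return self.grid_energies.shape[0]

    @property
    def n_samples(self) -> int:
        return self.grid_energies.shape[1]

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.n_samples) * (360.0 / self.n_samples)

    def _build_splines(self):
        x = np.append(self.grid, 360.0)
        self._splines = []
        for row in self.grid_energies:
            y = np.append(row, row[0])  # periodic closure
            self._splines.append(CubicSpline(x, y, bc_type="periodic"))

    def evaluate_batch(self, angles_deg: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(angles_deg, float)) % 360.0
        if a.shape[1] != self.n_dihedrals:
            raise ValueError(
                f"configuration has {a.shape[1]} angles, model has {self.n_dihedrals}"
            )
        total = np.full(a.shape[0], self.offset, dtype=float)
        if self.kind == "cubic":
            if self._splines is None:
                self._build_splines()
            for d, spl in enumerate(self._splines):
                total += spl(a[:, d])
        else:
            x = np.append(self.grid, 360.0)
            for d in range(self.n_dihedrals):
                y = np.append(self.grid_energies[d], self.grid_energies[d, 0])
                total += np.interp(a[:, d], x, y)
        return total

    def evaluate(self, angles_deg) -> float:
        return float(self.evaluate_batch(np.atleast_2d(angles_deg))[0])

    def to_dict(self) -> dict:
        return {
            "kind": "tabulated",
            "interpolation": self.kind,
            "units": "kcal/mol, degrees",
            "grid_energies": self.grid_energies.tolist(),
            "offset": float(self.offset),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TabulatedDihedralModel":
        return cls(np.array(d["grid_energies"]), d["offset"], d["interpolation"])


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    if d["kind"] == "fourier":
        return FourierDihedralModel.from_dict(d)
    if d["kind"] == "tabulated":
        return TabulatedDihedralModel.from_dict(d)
    raise ValueError(f"unknown model kind {d['kind']!r}")


# -- scan parameterization ----------------------------------------------------


def _fit_fourier_profile(grid_deg: np.ndarray, energies: np.ndarray):
    """Least-squares fit of one torsion profile to the four-term Fourier form.

    The profile is fit as c0 + Σ_m (a_m cos mφ + b_m sin mφ), m = 1..4,
    then re-expressed as amplitudes/phases of the standard form.  A zero
    amplitude leaves the phase at 0 by convention.  Returns
    (V[4], φ[4], residual_constant) where residual_constant is the part
    of c0 not accounted for by the Σ V_m/2 intrinsic constant.
    """
    phi = np.radians(grid_deg)
    cols = [np.ones_like(phi)]
    for m in range(1, 5):
        cols.append(np.cos(m * phi))
        cols.append(np.sin(m * phi))
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, energies, rcond=None)
    c0 = coef[0]
    V = np.zeros(4)
    ph = np.zeros(4)
    for m in range(1, 5):
        a, b = coef[2 * m - 1], coef[2 * m]
        # V_m/2 · s_m · cos(mφ − φ_m) = V_m/2 · s_m (cos φ_m cos mφ + sin φ_m sin mφ)
        s = _SIGNS[m - 1]
        amp = 2.0 * np.hypot(a, b)
        V[m - 1] = amp
        if amp > 1e-12:
            ph[m - 1] = np.degrees(np.arctan2(s * b, s * a)) % 360.0
    residual_constant = c0 - 0.5 * V.sum()
    return V, ph, residual_constant


class _CountingOracle:
    def __init__(self, fn):
        self.fn = fn
        self.calls = 0

    def __call__(self, angles):
        self.calls += 1
        try:
            e = float(self.fn(np.asarray(angles, float)))
        except Exception as exc:  # surface the offending configuration
            raise OracleError(f"oracle failed at configuration {angles}: {exc}") from exc
        if not np.isfinite(e):
            raise OracleError(f"oracle returned non-finite energy at {angles}")
        return e


def scan_parameterize(oracle, n_dihedrals: int, n_samples: int = 72,
                      mode: str = "fourier", reference_config=None,
                      interpolation: str = "cubic"):
    """Parameterize an uncorrelated dihedral model by independent 1-D scans.

    Each of the n_d torsions is scanned on an equally spaced ``n_samples``
    grid over [0, 360) with every other torsion held at
    ``reference_config`` — exactly n_s·n_d oracle evaluations.  Per-
    dihedral profiles are baseline-shifted (any per-term constant is
    degenerate with the global offset) and either least-squares fit to
    the four-term Fourier form or stored as a table; the global offset is
    then set so the model's minimum over the scan grid is zero.

    If ``reference_config`` is None, a coarse sequential pre-scan (12
    points per dihedral) locates a per-dihedral argmin first, at the cost
    of 12·n_d additional oracle calls.

    Parameters
    ----------
    oracle : callable(angles_deg: (n_d,) array) -> energy in kcal/mol
    mode : 'fourier' or 'tabulated'
    """
    if n_samples < 8:
        raise ValueError("n_samples must be at least 8")
    if mode not in ("fourier", "tabulated"):
        raise ValueError(f"unknown mode {mode!r}")
    counted = _CountingOracle(oracle)
    n_d = int(n_dihedrals)

    if reference_config is None:
        ref = np.zeros(n_d)
        coarse = np.arange(12) * 30.0
        for d in range(n_d):
            probe = np.tile(ref, (12, 1))
            probe[:, d] = coarse
            es = [counted(row) for row in probe]
            ref[d] = coarse[int(np.argmin(es))]
    else:
        ref = np.asarray(reference_config, float).copy()
        if ref.shape[0] != n_d:
            raise ValueError("reference_config length does not match n_dihedrals")

    grid = np.arange(n_samples) * (360.0 / n_samples)
    profiles = np.empty((n_d, n_samples))
    for d in range(n_d):
        conf = ref.copy()
        for s, ang in enumerate(grid):
            conf[d] = ang
            profiles[d, s] = counted(conf)
        profiles[d] -= profiles[d].min()  # baseline; folded into the offset

    if mode == "tabulated":
        model = TabulatedDihedralModel(profiles, offset=0.0, kind=interpolation)
        per_d_min = profiles.min(axis=1)  # zero by construction
        model.offset = -float(per_d_min.sum())
    else:
        V = np.empty((n_d, 4))
        ph = np.empty((n_d, 4))
        for d in range(n_d):
            V[d], ph[d], _ = _fit_fourier_profile(grid, profiles[d])
        # offset so the separable minimum over the scan grid is zero (any
        # fitted constants are degenerate with it and simply dropped)
        phi = np.radians(grid)[:, None] * _ORDERS[None, :]
        per_d_min = np.empty(n_d)
        for d in range(n_d):
            vals = (0.5 * V[d] * (1 + _SIGNS * np.cos(phi - np.radians(ph[d])))).sum(axis=1)
            per_d_min[d] = vals.min()
        model = FourierDihedralModel(V, ph, offset=-float(per_d_min.sum()))
    model.oracle_calls = counted.calls
    return model
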