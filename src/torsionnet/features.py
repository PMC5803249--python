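"""Fourier feature encoding of dihedral configurations.

The network input for a conformation is, per dihedral: the raw angle
(degrees, canonical [0, 360)) followed by (sin kα, cos kα) for each
periodicity k in the encoding.  The default periodicity set is
{0.5} ∪ {1, 2, …, 10} — 11 values, hence 23 features per dihedral.

The half-integer periodicity k = 0.5 is not 360°-periodic; it is made
well defined by always encoding the canonical representative in
[0, 360).  Consequently angles just below 360° and just above 0° agree
on every integer-k feature but flip the sign of the k = 0.5 cosine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import canonical_angle

__all__ = ["FeatureEncoding", "encode", "encode_batch"]

DEFAULT_PERIODICITIES = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)


@dataclass(frozen=True)
class FeatureEncoding:
    """Parameters of the angle → feature-vector map."""

    periodicities: tuple = DEFAULT_PERIODICITIES
    include_raw_angle: bool = True

    def __post_init__(self):
        ks = tuple(float(k) for k in self.periodicities)
        if any(k <= 0 for k in ks):
            raise ValueError("periodicities must be positive")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("periodicities must be strictly increasing")
        object.__setattr__(self, "periodicities", ks)

    @property
    def features_per_dihedral(self) -> int:
        return int(self.include_raw_angle) + 2 * len(self.periodicities)

    def feature_dim(self, n_dihedrals: int) -> int:
        return n_dihedrals * self.features_per_dihedral

    def to_dict(self) -> dict:
        return {
            "periodicities": list(self.periodicities),
            "include_raw_angle": self.include_raw_angle,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FeatureEncoding":
        return cls(tuple(data["periodicities"]), bool(data["include_raw_angle"]))


def encode_batch(angles_deg: np.ndarray, encoding: FeatureEncoding | None = None
                 ) -> np.ndarray:
    """Encode an (n_samples, n_d) array of angles into (n_samples, feature_dim).

    Per dihedral, in fixed order: canonical angle (if enabled), then
    sin(kα), cos(kα) for each periodicity k.
    """
    if encoding is None:
        encoding = FeatureEncoding()
    a = canonical_angle(np.atleast_2d(np.asarray(angles_deg, float)))
    n, n_d = a.shape
    rad = np.radians(a)
    blocks = []
    for d in range(n_d):
        cols = []
        if encoding.include_raw_angle:
            cols.append(a[:, d])
        for k in encoding.periodicities:
            cols.append(np.sin(k * rad[:, d]))
            cols.append(np.cos(k * rad[:, d]))
        blocks.append(np.column_stack(cols))
    return np.hstack(blocks)


def encode(angles_deg, encoding: FeatureEncoding | None = None) -> np.ndarray:
    """Encode a single configuration (length-n_d vector) into a feature vector."""
    return encode_batch(np.atleast_2d(angles_deg), encoding)[0]
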