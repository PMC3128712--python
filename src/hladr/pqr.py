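"""PQR point-charge structures (PDB-like records with charge and radius).

Only the whitespace-separated dialect is handled: for every ``ATOM`` /
``HETATM`` record the last five fields are x, y, z (Angstrom), charge
(elementary charges) and radius (Angstrom).  Other record types are
ignored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np


class PQRFormatError(ValueError):
    pass


@dataclass
class ChargeSystem:
    """Point charges with radii, the input to the electrostatics solver."""

    coords: np.ndarray  # (n, 3) Angstrom
    charges: np.ndarray  # (n,) elementary charges
    radii: np.ndarray  # (n,) Angstrom
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        n = len(self.charges)
        if self.coords.shape != (n, 3) or self.radii.shape != (n,):
            raise ValueError("coords, charges and radii must agree in length")
        if not np.isfinite(self.coords).all() or not np.isfinite(self.charges).all():
            raise ValueError("non-finite coordinate or charge")
        if (self.radii < 0).any() or not np.isfinite(self.radii).all():
            raise ValueError("radii must be finite and non-negative")
        if not self.names:
            self.names = [f"Q{i + 1}" for i in range(n)]

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def with_charges(self, charges) -> "ChargeSystem":
        """Same geometry (positions and radii), different charges."""
        return ChargeSystem(
            coords=self.coords.copy(),
            charges=np.asarray(charges, dtype=float),
            radii=self.radii.copy(),
            names=list(self.names),
        )


def read_pqr(stream) -> ChargeSystem:
    """Parse a PQR stream (or string); malformed records report their line."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    coords, charges, radii, names = [], [], [], []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or not (line.startswith("ATOM") or line.startswith("HETATM")):
            continue
        tokens = line.split()
        if len(tokens) < 8:
            raise PQRFormatError(f"line {lineno}: too few fields for a PQR record")
        try:
            x, y, z, q, r = (float(t) for t in tokens[-5:])
        except ValueError:
            raise PQRFormatError(
                f"line {lineno}: could not parse x y z charge radius "
                f"from {tokens[-5:]}"
            ) from None
        if r < 0:
            raise PQRFormatError(f"line {lineno}: negative radius {r}")
        coords.append((x, y, z))
        charges.append(q)
        radii.append(r)
        names.append(tokens[2] if len(tokens) > 2 else f"Q{lineno}")
    return ChargeSystem(
        coords=np.array(coords, dtype=float).reshape(-1, 3),
        charges=np.array(charges, dtype=float),
        radii=np.array(radii, dtype=float),
        names=names,
    )


def write_pqr(system: ChargeSystem, stream=None) -> str:
    out = io.StringIO()
    for i in range(len(system)):
        x, y, z = system.coords[i]
        out.write(
            f"ATOM  {i + 1:5d} {system.names[i]:<4s} MOL     1    "
            f"{x:10.4f} {y:10.4f} {z:10.4f} {system.charges[i]:8.4f} "
            f"{system.radii[i]:7.4f}\n"
        )
    out.write("END\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text
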