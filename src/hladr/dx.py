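"""OpenDX scalar-grid I/O for potential maps (APBS/DelPhi ecosystem)."""

from __future__ import annotations

import io

import numpy as np

from .pb import PotentialMap


def write_dx(pmap: PotentialMap, stream=None, name: str = "potential") -> str:
    """Serialize a :class:`PotentialMap` as an OpenDX scalar grid (kT/e)."""
    nx, ny, nz = pmap.npts
    out = io.StringIO()
    out.write(f"# {name} (kT/e)\n")
    out.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
    out.write(
        "origin {:.6e} {:.6e} {:.6e}\n".format(*pmap.origin)
    )
    h = pmap.spacing
    out.write(f"delta {h:.6e} 0.000000e+00 0.000000e+00\n")
    out.write(f"delta 0.000000e+00 {h:.6e} 0.000000e+00\n")
    out.write(f"delta 0.000000e+00 0.000000e+00 {h:.6e}\n")
    out.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
    out.write(
        f"object 3 class array type double rank 0 items {nx * ny * nz} "
        "data follows\n"
    )
    flat = pmap.values.ravel(order="C")
    for i in range(0, flat.size, 3):
        out.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
    out.write('attribute "dep" string "positions"\n')
    out.write(f'object "{name}" class field\n')
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_dx(stream) -> PotentialMap:
    """Read an OpenDX scalar grid with a uniform diagonal spacing."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    counts = None
    origin = None
    deltas: list[list[float]] = []
    values: list[float] = []
    n_items = None
    reading = False
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if reading:
            if line.startswith("attribute") or line.startswith("object"):
                reading = False
                continue
            values.extend(float(t) for t in line.split())
            continue
        if line.startswith("object 1"):
            counts = [int(t) for t in line.split()[-3:]]
        elif line.startswith("origin"):
            origin = [float(t) for t in line.split()[1:4]]
        elif line.startswith("delta"):
            deltas.append([float(t) for t in line.split()[1:4]])
        elif line.startswith("object 3"):
            n_items = int(line.split()[-3])
            reading = True
    if counts is None or origin is None or len(deltas) != 3:
        raise ValueError("not a recognizable OpenDX scalar grid")
    d = np.array(deltas)
    off = d - np.diag(np.diag(d))
    if np.abs(off).max() > 1e-12:
        raise ValueError("only axis-aligned (diagonal) deltas are supported")
    diag = np.diag(d)
    if np.abs(diag - diag[0]).max() > 1e-9 * abs(diag[0]):
        raise ValueError("only uniform cubic spacing is supported")
    if n_items is not None and len(values) != n_items:
        raise ValueError(
            f"expected {n_items} data items, found {len(values)}"
        )
    arr = np.array(values).reshape(counts, order="C")
    return PotentialMap(values=arr, origin=np.array(origin), spacing=float(diag[0]))
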