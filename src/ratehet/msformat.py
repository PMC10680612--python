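"""ms-style haplotype text blocks with a TSV sidecar.

The main file is a standard ms block ("//", "segsites:", "positions:"
and 0/1 haplotype rows) with positions normalised to [0, 1); the
sidecar TSV carries what ms cannot: integer site coordinates, site
classes and selection coefficients.
"""

from __future__ import annotations

import numpy as np

from .architecture import CLASS_CODES, CLASS_NAMES
from .simulate import ReplicateResult

__all__ = ["write_ms", "read_ms", "write_sidecar", "read_sidecar"]


def write_ms(rep: ReplicateResult, path=None) -> str:
    L = rep.total_length
    seed = -1 if rep.seed is None else rep.seed
    lines = [f"ms {rep.n} 1 -L {L} -seed {seed} -Q {rep.Q:g}", "", "//",
             f"segsites: {rep.S}"]
    if rep.S:
        pos = " ".join(f"{p / L:.10f}" for p in rep.positions)
        lines.append(f"positions: {pos}")
        for row in rep.haplotypes:
            lines.append("".join("1" if x else "0" for x in row))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_sidecar(rep: ReplicateResult, path=None) -> str:
    lines = [f"# total_length={rep.total_length} n_fixed={rep.n_fixed}",
             "position\tsite_class\ts"]
    for p, c, s in zip(rep.positions, rep.site_class, rep.s):
        lines.append(f"{p}\t{CLASS_NAMES[int(c)]}\t{s:.17g}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_sidecar(source):
    text = source
    if "\n" not in str(source):
        with open(source) as fh:
            text = fh.read()
    lines = text.splitlines()
    meta = dict(kv.split("=") for kv in lines[0].lstrip("# ").split())
    pos, cls, s = [], [], []
    for line in lines[2:]:
        if not line.strip():
            continue
        p, c, sv = line.split("\t")
        pos.append(int(p))
        cls.append(CLASS_CODES[c])
        s.append(float(sv))
    return (np.array(pos, dtype=np.int64), np.array(cls, dtype=np.uint8),
            np.array(s), int(meta["total_length"]),
            int(meta.get("n_fixed", 0)))


def read_ms(source, sidecar=None) -> ReplicateResult:
    """Parse one ms block (text or path); the sidecar, when given,
    restores integer positions, site classes and s exactly."""
    text = source
    if "\n" not in str(source):
        with open(source) as fh:
            text = fh.read()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("ms "):
        raise ValueError("malformed ms block: missing header")
    header = lines[0].split()
    n = int(header[1])
    opts = {header[i]: header[i + 1] for i in range(3, len(header) - 1, 2)}
    L = int(opts.get("-L", 0))
    seed = int(opts.get("-seed", -1))
    seed = None if seed < 0 else seed
    Q = float(opts.get("-Q", 1))
    try:
        i = lines.index("//")
    except ValueError:
        raise ValueError("malformed ms block: missing //")
    seg_line = lines[i + 1]
    if not seg_line.startswith("segsites:"):
        raise ValueError("malformed ms block: missing segsites")
    S = int(seg_line.split()[1])
    if S == 0:
        positions = np.empty(0, dtype=np.int64)
        hap = np.empty((n, 0), dtype=np.uint8)
    else:
        pos_line = lines[i + 2]
        if not pos_line.startswith("positions:"):
            raise ValueError("malformed ms block: missing positions")
        rel = np.array([float(x) for x in pos_line.split()[1:]])
        if len(rel) != S:
            raise ValueError("malformed ms block: positions != segsites")
        if np.any(np.diff(rel) <= 0):
            raise ValueError("malformed ms block: positions not increasing")
        positions = np.round(rel * L).astype(np.int64)
        rows = lines[i + 3:i + 3 + n]
        if len(rows) < n or any(len(r) != S for r in rows):
            raise ValueError("malformed ms block: haplotype rows")
        hap = np.array([[int(ch) for ch in r] for r in rows], dtype=np.uint8)
    if sidecar is not None:
        positions, cls, s, L_sc, n_fixed = read_sidecar(sidecar)
        if L and L_sc != L:
            raise ValueError("sidecar length disagrees with ms header")
        L = L_sc
    else:
        from .architecture import INTERGENIC
        cls = np.full(S, INTERGENIC, dtype=np.uint8)
        s = np.zeros(S)
        n_fixed = 0
    return ReplicateResult(positions, hap, cls, s, L, seed, Q,
                           n_fixed=n_fixed)
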