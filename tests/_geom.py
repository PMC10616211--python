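"""Shared test helpers: tiny hand-built structures and the toy assembly map."""

import numpy as np

from tetherdock.structio import Structure

ASSEMBLY_MAP = {"REC": ("A", "B"), "LIG": ("C", "D")}


def make_points(points, chains=None, resnums=None, resnames=None, atomnames=None):
    xyz = np.asarray(points, dtype=float)
    n = xyz.shape[0]
    return Structure(
        chain=np.array(chains or ["A"] * n, dtype=object),
        resnum=np.array(resnums or range(1, n + 1), dtype=int),
        icode=np.array([""] * n, dtype=object),
        resname=np.array(resnames or ["GLY"] * n, dtype=object),
        atomname=np.array(atomnames or ["CA"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        xyz=xyz,
    )
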