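"""Optional demo inputs: ten public covalent-inhibitor complexes.

These PDB entries cover structurally diverse switch-II-pocket ligands and
receptor conformations and form a 10x10 cross-docking matrix (10
self-docking + 90 cross-docking jobs).  Nothing in the package or its
tests depends on them; they are a convenience for users with network
access who want to exercise the pipeline on real structures.

The classic flexible/blocking residue lists for this target (chain A,
author numbering) are included as a starting site specification; profiling
your own ensemble is preferred.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

from .flexprofile import BindingSiteSpec

DEMO_PDB_CODES = ["5F2E", "5V9U", "6OIM", "6P8X", "6UT0",
                  "6T5B", "6TAN", "8DNI", "8DNJ", "8DNK"]

_RCSB = "https://files.rcsb.org/download/{code}.pdb"


def demo_site_spec(chain: str = "A") -> BindingSiteSpec:
    """Flexible/blocking residue lists for the demo target.

    Flexible: the switch-II loop and alpha-2 helix span (58-74) plus
    K88, D92, H95, Y96, Q99, R102, V103, the reactive C12, and E37.
    Blocking: E62, Y64, R68, M72, H95.
    """
    flexible = ([(chain, i) for i in range(58, 75)]
                + [(chain, i) for i in (88, 92, 95, 96, 99, 102, 103, 12, 37)])
    blocking = [(chain, i) for i in (62, 64, 68, 72, 95)]
    return BindingSiteSpec(reactive_residue=(chain, 12),
                           flexible_residues=flexible,
                           blocking_residues=blocking)


def download_demo(outdir: str | Path, codes: list[str] | None = None) -> list[Path]:
    """Fetch the demo PDB files (network required); returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for code in codes or DEMO_PDB_CODES:
        dest = outdir / f"{code}.pdb"
        if not dest.exists():
            urllib.request.urlretrieve(_RCSB.format(code=code), dest)
        written.append(dest)
    return written
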