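"""Gene-set collections in GMT format.

Ships a small fixed toy collection (synthetic stand-in for the large public
KEGG/GO/REACTOME/MSigDB collections, which are external resources) used by
the synthetic generator and the permutation gene-set tests.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .types import GeneSet


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        sets.append(GeneSet(name=fields[0], description=fields[1], genes=tuple(fields[2:])))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.description, *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def bundled_gene_sets() -> list[GeneSet]:
    """The toy collection shipped with the package."""
    with resources.as_file(resources.files("tcrbm.data") / "genesets.gmt") as p:
        return read_gmt(p)
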