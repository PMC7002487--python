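"""Minimal GenePop reader/writer for codominant microsatellite genotypes.

Supports single-population files with 2- or 3-digit allele codes, comma
after the individual name, loci listed one per line (or comma-separated on
one line), and 00/000 for missing alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GenotypeTable", "read_genepop", "write_genepop"]


@dataclass
class GenotypeTable:
    """Two alleles per individual per locus; 0 encodes missing.

    ``alleles[i, l]`` is the pair of integer allele labels of individual
    ``ids[i]`` at ``loci[l]``.  Missing data is all-or-nothing per locus
    per individual: (0, 0).
    """

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n, L, 2) int

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=int)
        n, L, two = self.alleles.shape
        if n != len(self.ids) or L != len(self.loci) or two != 2:
            raise ValueError("alleles array shape does not match ids/loci")
        half = (self.alleles == 0).sum(axis=2)
        if np.any(half == 1):
            raise ValueError("half-missing genotype: missing data must be per-locus")

    @property
    def n(self) -> int:
        return len(self.ids)

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean, True where the genotype is missing."""
        return (self.alleles == 0).all(axis=2)

    def subset(self, ids: list[str]) -> "GenotypeTable":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = [pos[str(i)] for i in ids]
        return GenotypeTable([str(i) for i in ids], list(self.loci), self.alleles[idx])


def read_genepop(path) -> GenotypeTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty GenePop file")
    body = lines[1:]  # first line is the title
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = body[i].strip()
        if chunk:
            loci.extend(l.strip() for l in chunk.split(",") if l.strip())
        i += 1
    if i == len(body):
        raise ValueError("GenePop file has no 'Pop' line")
    ids, rows = [], []
    for ln in body[i + 1:]:
        ln = ln.strip()
        if not ln:
            continue
        if ln.lower() == "pop":
            raise ValueError("multi-population GenePop files are not supported")
        if "," not in ln:
            raise ValueError(f"malformed GenePop individual line: {ln!r}")
        name, geno = ln.split(",", 1)
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(
                f"individual {name.strip()!r} has {len(codes)} genotypes for {len(loci)} loci"
            )
        pair_row = []
        for c in codes:
            if len(c) not in (4, 6) or not c.isdigit():
                raise ValueError(f"malformed genotype code {c!r}")
            half = len(c) // 2
            pair_row.append((int(c[:half]), int(c[half:])))
        ids.append(name.strip())
        rows.append(pair_row)
    if not ids:
        raise ValueError("GenePop file has no individuals")
    return GenotypeTable(ids=ids, loci=loci, alleles=np.array(rows, dtype=int))


def write_genepop(table: GenotypeTable, path, title: str = "finsoc genotypes") -> None:
    width = 3 if table.alleles.max() > 99 else 2
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        fh.write("Pop\n")
        for i, ind in enumerate(table.ids):
            codes = [
                f"{a:0{width}d}{b:0{width}d}" for a, b in table.alleles[i]
            ]
            fh.write(f"{ind} ,  " + " ".join(codes) + "\n")
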