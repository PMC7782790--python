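"""Karyotype representation: chromosome names, lengths and genome fractions.

Every per-chromosome computation in this package (mismatch simulation,
segregation classification) is parameterised by a :class:`ChromosomeSet`,
which carries ordered chromosome lengths and the fraction ``f_i`` of the
genome each chromosome represents.  Built-in tables are provided for the
budding-yeast S288C reference (16 nuclear chromosomes) and the human GRCh38
primary assembly (chr1-22, X, Y); custom tables, e.g. repeat-masked lengths,
can be loaded from fai-style TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ChromosomeSet", "builtin_karyotype", "load_chromosome_table"]

# S288C (R64/sacCer3) nuclear chromosome lengths, bp.
_YEAST_S288C = [
    ("chrI", 230218), ("chrII", 813184), ("chrIII", 316620),
    ("chrIV", 1531933), ("chrV", 576874), ("chrVI", 270161),
    ("chrVII", 1090940), ("chrVIII", 562643), ("chrIX", 439888),
    ("chrX", 745751), ("chrXI", 666816), ("chrXII", 1078177),
    ("chrXIII", 924431), ("chrXIV", 784333), ("chrXV", 1091291),
    ("chrXVI", 948066),
]

# GRCh38 primary assembled chromosomes, bp (no mitochondrion, no scaffolds).
_HUMAN_GRCH38 = [
    ("chr1", 248956422), ("chr2", 242193529), ("chr3", 198295559),
    ("chr4", 190214555), ("chr5", 181538259), ("chr6", 170805979),
    ("chr7", 159345973), ("chr8", 145138636), ("chr9", 138394717),
    ("chr10", 133797422), ("chr11", 135086622), ("chr12", 133275309),
    ("chr13", 114364328), ("chr14", 107043718), ("chr15", 101991189),
    ("chr16", 90338345), ("chr17", 83257441), ("chr18", 80373285),
    ("chr19", 58617616), ("chr20", 64444167), ("chr21", 46709983),
    ("chr22", 50818468), ("chrX", 156040895), ("chrY", 57227415),
]

_BUILTINS = {
    "yeast_s288c": _YEAST_S288C,
    "human_grch38": _HUMAN_GRCH38,
}


@dataclass(frozen=True)
class ChromosomeSet:
    """An ordered set of chromosomes with lengths and genome fractions.

    Parameters
    ----------
    names : tuple of str
        Unique chromosome identifiers, order preserved from the source.
    lengths_bp : tuple of int
        Positive chromosome lengths in base pairs.
    ploidy : int
        Copies of each chromosome per cell (1 haploid, 2 diploid).

    Notes
    -----
    ``fractions[i] = lengths_bp[i] / sum(lengths_bp)`` is recomputed from the
    lengths on construction, so it always sums to 1 (within 1e-12) and is
    invariant under a uniform rescaling of all lengths.
    """

    names: tuple[str, ...]
    lengths_bp: tuple[int, ...]
    ploidy: int = 2
    fractions: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("ChromosomeSet needs at least one chromosome")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        if len(self.names) != len(self.lengths_bp):
            raise ValueError("names and lengths differ in length")
        if any(l <= 0 for l in self.lengths_bp):
            raise ValueError("chromosome lengths must be positive")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        total = float(sum(self.lengths_bp))
        object.__setattr__(
            self, "fractions", tuple(l / total for l in self.lengths_bp)
        )

    @property
    def n_chromosomes(self) -> int:
        return len(self.names)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths_bp))

    def length_of(self, name: str) -> int:
        return self.lengths_bp[self.names.index(name)]

    def fractions_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def copy_fractions(self) -> np.ndarray:
        """Per-chromosome-copy fractions: each haploid fraction repeated
        ``ploidy`` times (one entry per physical chromosome copy)."""
        return np.repeat(self.fractions_array(), self.ploidy)

    def sum_squared_fractions(self) -> float:
        """Sum of squared haploid genome fractions, ``sum_i f_i**2``.

        This is the karyotype term in the closed-form index of dispersion of
        the Poisson-binomial segregation process (see :mod:`.simulate`).
        """
        f = self.fractions_array()
        return float(np.sum(f * f))

    def with_ploidy(self, ploidy: int) -> "ChromosomeSet":
        return ChromosomeSet(self.names, self.lengths_bp, ploidy)

    def to_tsv(self, path: str | Path) -> None:
        """Write a 2-column fai-style TSV (name, length)."""
        with open(path, "w") as fh:
            for name, length in zip(self.names, self.lengths_bp):
                fh.write(f"{name}\t{length}\n")


def builtin_karyotype(name: str, ploidy: int = 2) -> ChromosomeSet:
    """Return an embedded reference karyotype.

    Parameters
    ----------
    name : {"yeast_s288c", "human_grch38"}
        ``yeast_s288c``: the 16 S288C nuclear chromosomes (~12.07 Mb).
        ``human_grch38``: the 24 GRCh38 reference chromosomes chr1-22, X, Y
        (~3.09 Gb).  Mitochondrial genomes and unplaced scaffolds are
        excluded.
    ploidy : int
        Copies of each chromosome (default 2, diploid).
    """
    try:
        table = _BUILTINS[name]
    except KeyError:
        raise ValueError(
            f"unknown karyotype {name!r}; available: {sorted(_BUILTINS)}"
        ) from None
    names, lengths = zip(*table)
    return ChromosomeSet(names, lengths, ploidy)


def load_chromosome_table(path: str | Path, ploidy: int = 2) -> ChromosomeSet:
    """Load a karyotype from a fai-style TSV.

    The first two columns are chromosome name and length; extra columns
    (as produced by ``samtools faidx``) are ignored.  File order is
    preserved.  Duplicate names, non-positive lengths and empty files are
    rejected.
    """
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns")
            try:
                length = int(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: length {parts[1]!r} is not an integer"
                ) from None
            names.append(parts[0])
            lengths.append(length)
    if not names:
        raise ValueError(f"{path}: empty chromosome table")
    return ChromosomeSet(tuple(names), tuple(lengths), ploidy)
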