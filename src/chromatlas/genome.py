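"""Assemblies, fixed-width genomic bins, reference tracks, and contact-pair I/O.

Coordinate conventions
----------------------
Contact positions are 1-based (the pairs-file convention) everywhere in
memory; bins are 0-based half-open.  Conversion between the two happens in
exactly one place, :meth:`BinIndex.locate`, so no other code needs to think
about off-by-one arithmetic.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "Assembly",
    "BinIndex",
    "BinTrack",
    "CellContacts",
    "load_assembly",
    "make_bins",
    "cpg_density_track",
    "read_pairs",
    "write_pairs",
]


def _open_text(path, mode: str = "rt"):
    """Open a text file, transparently decompressing ``.gz`` paths."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class Assembly:
    """An ordered set of chromosomes with lengths and sex-chromosome flags.

    Parameters
    ----------
    names : tuple of str
        Chromosome names in declared order.
    lengths : tuple of int
        Chromosome lengths in base pairs, parallel to ``names``.
    sex_chroms : frozenset of str
        Names treated as X-like (single copy in males, excluded from
        autosomal statistics).
    """

    names: tuple
    lengths: tuple
    sex_chroms: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.names) == 0:
            raise ValueError("no chromosomes")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome name")
        if len(self.lengths) != len(self.names):
            raise ValueError("names and lengths differ in length")
        for name, length in zip(self.names, self.lengths):
            if length <= 0:
                raise ValueError(f"non-positive length for {name!r}: {length}")
        if not self.sex_chroms <= set(self.names):
            raise ValueError("sex_chroms not a subset of chromosome names")

    @property
    def n_chroms(self) -> int:
        return len(self.names)

    @property
    def autosomes(self) -> tuple:
        return tuple(n for n in self.names if n not in self.sex_chroms)

    @property
    def index(self) -> dict:
        """Mapping from chromosome name to ordinal."""
        return {n: i for i, n in enumerate(self.names)}

    @property
    def lengths_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=np.int64)

    @property
    def sex_mask(self) -> np.ndarray:
        """Boolean mask over chromosome ordinals, True for sex chromosomes."""
        return np.array([n in self.sex_chroms for n in self.names], dtype=bool)

    @classmethod
    def from_dict(cls, lengths: dict, sex_chroms: Iterable | None = None) -> "Assembly":
        names = tuple(lengths)
        if sex_chroms is None:
            sex_chroms = [n for n in names if n.lower() in ("chrx", "x")]
        return cls(names, tuple(lengths[n] for n in names), frozenset(sex_chroms))


def load_assembly(path, sex_chroms: Iterable | None = None) -> Assembly:
    """Parse a two-column ``name\\tlength`` chromosome-size table.

    Chromosomes named ``chrX`` or ``X`` (case-insensitive) are flagged as sex
    chromosomes unless ``sex_chroms`` overrides the default.
    """
    lengths: dict = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected 'name<TAB>length'")
            name = parts[0]
            if name in lengths:
                raise ValueError(f"line {lineno}: duplicate chromosome name {name!r}")
            length = int(parts[1])
            if length <= 0:
                raise ValueError(f"line {lineno}: non-positive length for {name!r}")
            lengths[name] = length
    if not lengths:
        raise ValueError("no chromosomes")
    return Assembly.from_dict(lengths, sex_chroms)


@dataclass(frozen=True)
class BinIndex:
    """Fixed-width tiling of an assembly into 0-based half-open bins.

    Each chromosome is covered by ``ceil(L / bin_size)`` bins; the last bin of
    a chromosome may be short.  Global bin ordinals run chromosome by
    chromosome in assembly order.
    """

    assembly: Assembly
    bin_size: int

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins_per_chrom(self) -> np.ndarray:
        L = self.assembly.lengths_array
        return -(-L // self.bin_size)  # ceil division

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Global ordinal of the first bin of each chromosome."""
        n = self.n_bins_per_chrom
        return np.concatenate([[0], np.cumsum(n)[:-1]])

    @property
    def n_bins(self) -> int:
        return int(self.n_bins_per_chrom.sum())

    @property
    def bin_chrom(self) -> np.ndarray:
        """Chromosome ordinal of each bin."""
        return np.repeat(np.arange(self.assembly.n_chroms), self.n_bins_per_chrom)

    @property
    def bin_starts(self) -> np.ndarray:
        n = self.n_bins_per_chrom
        within = np.concatenate([np.arange(k) for k in n])
        return within * self.bin_size

    @property
    def bin_ends(self) -> np.ndarray:
        L = self.assembly.lengths_array
        return np.minimum(self.bin_starts + self.bin_size, L[self.bin_chrom])

    @property
    def bin_widths(self) -> np.ndarray:
        return self.bin_ends - self.bin_starts

    @property
    def autosomal_mask(self) -> np.ndarray:
        """Boolean mask over global bin ordinals, True for autosomal bins."""
        return ~self.assembly.sex_mask[self.bin_chrom]

    def bins(self):
        """Yield (chrom_name, start, end) for every bin in global order."""
        names = self.assembly.names
        for c, s, e in zip(self.bin_chrom, self.bin_starts, self.bin_ends):
            yield names[c], int(s), int(e)

    def locate(self, chrom, pos_1based):
        """Global ordinal(s) of the bin(s) containing 1-based position(s).

        ``chrom`` may be a name (str) or an array of chromosome ordinals;
        ``pos_1based`` a scalar or array.  Positions outside ``[1, L]`` raise.
        """
        if isinstance(chrom, str):
            try:
                ci = self.assembly.index[chrom]
            except KeyError:
                raise KeyError(f"unknown chromosome {chrom!r}") from None
            ci = np.asarray(ci)
        else:
            ci = np.asarray(chrom)
        pos = np.asarray(pos_1based, dtype=np.int64)
        L = self.assembly.lengths_array[ci]
        if np.any(pos < 1) or np.any(pos > L):
            raise ValueError("position out of chromosome range")
        ordinal = self.chrom_offsets[ci] + (pos - 1) // self.bin_size
        if ordinal.ndim == 0:
            return int(ordinal)
        return ordinal


def make_bins(assembly: Assembly, bin_size: int) -> BinIndex:
    """Tile ``assembly`` into fixed-width bins of ``bin_size`` base pairs."""
    return BinIndex(assembly, int(bin_size))


@dataclass
class BinTrack:
    """One scalar per bin of a :class:`BinIndex` (CpG density, compartment
    sign, mean scA/B, ...)."""

    bin_index: BinIndex
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.bin_index.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} does not match "
                f"{self.bin_index.n_bins} bins"
            )

    def to_bedgraph(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for (chrom, start, end), v in zip(self.bin_index.bins(), self.values):
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.10g}\n")

    @classmethod
    def from_bedgraph(cls, path, bin_index: BinIndex, kind: str = "generic") -> "BinTrack":
        values = np.full(bin_index.n_bins, np.nan)
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"line {lineno}: expected 4 bedGraph columns")
                chrom, start, _end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                ordinal = bin_index.locate(chrom, start + 1)
                values[ordinal] = value
        if np.isnan(values).any():
            raise ValueError("bedGraph does not cover every bin of the index")
        return cls(bin_index, values, kind)


class CellContacts:
    """One cell's chromatin contacts as parallel coordinate arrays.

    Contacts are stored canonically: ``chrom_a <= chrom_b`` in assembly order
    and ``pos_a <= pos_b`` for intra-chromosomal contacts.  Positions are
    1-based.
    """

    def __init__(
        self,
        cell_id: str,
        assembly: Assembly,
        chrom_a: np.ndarray,
        pos_a: np.ndarray,
        chrom_b: np.ndarray,
        pos_b: np.ndarray,
        meta: dict | None = None,
    ):
        self.cell_id = cell_id
        self.assembly = assembly
        ca = np.asarray(chrom_a, dtype=np.int32)
        cb = np.asarray(chrom_b, dtype=np.int32)
        pa = np.asarray(pos_a, dtype=np.int64)
        pb = np.asarray(pos_b, dtype=np.int64)
        if not (len(ca) == len(cb) == len(pa) == len(pb)):
            raise ValueError("coordinate arrays must have equal length")
        if len(ca) and (ca.max() >= assembly.n_chroms or cb.max() >= assembly.n_chroms):
            raise ValueError("contact references chromosome outside assembly")
        # canonical ordering
        swap = (ca > cb) | ((ca == cb) & (pa > pb))
        self.chrom_a = np.where(swap, cb, ca)
        self.chrom_b = np.where(swap, ca, cb)
        self.pos_a = np.where(swap, pb, pa)
        self.pos_b = np.where(swap, pa, pb)
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.chrom_a)

    @property
    def n_contacts(self) -> int:
        return len(self)

    @property
    def is_intra(self) -> np.ndarray:
        return self.chrom_a == self.chrom_b

    @property
    def intra_distances(self) -> np.ndarray:
        """Genomic distances of intra-chromosomal contacts only."""
        m = self.is_intra
        return (self.pos_b[m] - self.pos_a[m]).astype(np.int64)

    def subset(self, mask: np.ndarray) -> "CellContacts":
        return CellContacts(
            self.cell_id,
            self.assembly,
            self.chrom_a[mask],
            self.pos_a[mask],
            self.chrom_b[mask],
            self.pos_b[mask],
            self.meta,
        )

    def __repr__(self) -> str:
        return f"CellContacts({self.cell_id!r}, n={len(self)})"


def read_pairs(path, assembly: Assembly, cell_id: str | None = None) -> CellContacts:
    """Read a 4DN-style ``.pairs`` text file into a :class:`CellContacts`.

    Header lines start with ``#``; body columns are
    ``readID chr1 pos1 chr2 pos2 [strand1 strand2]``.  Strand columns are
    ignored.  Malformed lines and unknown chromosomes are reported with their
    line number.
    """
    idx = assembly.index
    ca, pa, cb, pb = [], [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"line {lineno}: expected at least 5 columns")
            try:
                c1, p1, c2, p2 = parts[1], int(parts[2]), parts[3], int(parts[4])
            except ValueError:
                raise ValueError(f"line {lineno}: malformed positions") from None
            try:
                ca.append(idx[c1])
                cb.append(idx[c2])
            except KeyError as e:
                raise ValueError(f"line {lineno}: unknown chromosome {e.args[0]!r}") from None
            pa.append(p1)
            pb.append(p2)
    if cell_id is None:
        cell_id = str(path)
    return CellContacts(
        cell_id,
        assembly,
        np.array(ca, dtype=np.int32),
        np.array(pa, dtype=np.int64),
        np.array(cb, dtype=np.int32),
        np.array(pb, dtype=np.int64),
    )


def write_pairs(cell: CellContacts, path) -> None:
    """Write contacts in 4DN ``.pairs`` text form (gzip if path ends ``.gz``)."""
    names = cell.assembly.names
    with _open_text(path, "wt") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chr1 pos1 chr2 pos2\n")
        for i in range(len(cell)):
            fh.write(
                f".\t{names[cell.chrom_a[i]]}\t{cell.pos_a[i]}"
                f"\t{names[cell.chrom_b[i]]}\t{cell.pos_b[i]}\n"
            )


def _count_cg_per_bin(seq: str, bin_index: BinIndex, chrom_ordinal: int) -> np.ndarray:
    """Count CG dinucleotides per bin of one chromosome.

    A CG straddling a bin boundary is credited to the bin of its first base.
    Case-insensitive; dinucleotides containing N are not counted.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_c = arr[:-1] == ord("C")
    is_g = arr[1:] == ord("G")
    cg_first_base = np.flatnonzero(is_c & is_g)  # 0-based position of the C
    n_bins = int(bin_index.n_bins_per_chrom[chrom_ordinal])
    counts = np.bincount(cg_first_base // bin_index.bin_size, minlength=n_bins)
    return counts[:n_bins]


def cpg_density_track(fasta_path, bin_index: BinIndex) -> BinTrack:
    """Per-bin CpG (CG dinucleotide) count divided by bin width.

    FASTA sequence names and lengths must match the assembly of
    ``bin_index``.
    """
    from pyfaidx import Fasta

    assembly = bin_index.assembly
    fasta = Fasta(str(fasta_path))
    values = np.zeros(bin_index.n_bins)
    offsets = bin_index.chrom_offsets
    nb = bin_index.n_bins_per_chrom
    for ci, name in enumerate(assembly.names):
        if name not in fasta:
            raise ValueError(f"chromosome {name!r} missing from FASTA")
        seq = str(fasta[name][:])
        if len(seq) != assembly.lengths[ci]:
            raise ValueError(
                f"length mismatch for {name!r}: FASTA {len(seq)}, "
                f"assembly {assembly.lengths[ci]}"
            )
        counts = _count_cg_per_bin(seq, bin_index, ci)
        sl = slice(int(offsets[ci]), int(offsets[ci] + nb[ci]))
        values[sl] = counts / bin_index.bin_widths[sl]
    return BinTrack(bin_index, values, kind="cpg_density")
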