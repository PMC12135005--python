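"""Phased haplotype matrices and VCF round-trip I/O.

:class:`HaplotypeDataset` is the substrate of the whole pipeline: a
haplotypes-by-variants 0/1 matrix (0 = ancestral, 1 = derived) with 1-based
physical positions, known region bounds, and a fixed haplotype-to-individual
pairing (consecutive haplotypes belong to one individual under diploid
pairing).

VCF conventions: genotypes are phased (``|`` separator), REF is the ancestral
allele (written ``A``), ALT the derived allele (written ``T``), positions are
1-based. Reading goes through cyvcf2; writing emits the nine fixed columns
plus one GT-only sample column per individual.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
from cyvcf2 import VCF

__all__ = ["HaplotypeDataset", "read_vcf", "write_haplotype_vcf"]

_ANCESTRAL_BASE = "A"
_DERIVED_BASE = "T"


@dataclass
class HaplotypeDataset:
    """Phased 0/1 haplotype matrix over a contiguous region [1, seq_length_bp].

    Parameters
    ----------
    haplotypes
        uint8 array of shape (n_haplotypes, n_sites); 0 ancestral, 1 derived.
    positions
        1-based physical positions, strictly increasing, one per matrix column.
    seq_length_bp
        Length of the region; positions must lie in [1, seq_length_bp].
    chrom
        Chromosome label used in VCF/BED round trips.
    ploidy
        Haplotype-to-individual pairing: haplotype ``i`` is copy ``i % ploidy``
        of individual ``i // ploidy``. Diploid (2) by default; 1 for haploid
        exports.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    seq_length_bp: int
    chrom: str = "22"
    ploidy: int = 2

    def __post_init__(self):
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.seq_length_bp = int(self.seq_length_bp)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D (haplotypes x sites)")
        if self.haplotypes.shape[1] != self.positions.shape[0]:
            raise ValueError(
                f"matrix has {self.haplotypes.shape[1]} sites but "
                f"{self.positions.shape[0]} positions"
            )
        if self.positions.size and (
            np.any(np.diff(self.positions) <= 0)
            or self.positions[0] < 1
            or self.positions[-1] > self.seq_length_bp
        ):
            raise ValueError(
                "positions must be strictly increasing and within [1, seq_length_bp]"
            )
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")

    # -- basic shape -------------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def derived_counts(self) -> np.ndarray:
        """Per-variant derived-allele count k."""
        return self.haplotypes.sum(axis=0, dtype=np.int64)

    def individual_of(self, hap_index: int) -> int:
        return hap_index // self.ploidy

    # -- manipulation ------------------------------------------------------
    def subset_sites(self, index) -> "HaplotypeDataset":
        """A new dataset restricted to the variant columns selected by ``index``."""
        return replace(
            self,
            haplotypes=self.haplotypes[:, index],
            positions=self.positions[index],
        )

    def copy(self) -> "HaplotypeDataset":
        return replace(
            self, haplotypes=self.haplotypes.copy(), positions=self.positions.copy()
        )

    def validate_segregating(self) -> None:
        """Raise unless every variant satisfies 1 <= k < n_haplotypes."""
        k = self.derived_counts
        if k.size and (k.min() < 1 or k.max() >= self.n_haplotypes):
            raise ValueError("dataset contains non-segregating variants")


def write_haplotype_vcf(ds: HaplotypeDataset, path) -> None:
    """Write ``ds`` as an uncompressed, phased VCF 4.2 file.

    One sample column per individual; diploid samples pair consecutive
    haplotypes into ``a|b`` genotypes. Deterministic: identical datasets
    produce byte-identical files.
    """
    if ds.n_sites == 0:
        raise ValueError("refusing to write a VCF with zero variants")
    if ds.n_haplotypes % ds.ploidy != 0:
        raise ValueError("haplotype count is not a multiple of the ploidy")
    n_ind = ds.n_haplotypes // ds.ploidy
    names = [f"ind_{i}" for i in range(n_ind)]
    sep = "|"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mshage\n")
        fh.write(f"##contig=<ID={ds.chrom},length={ds.seq_length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        H = ds.haplotypes
        for j in range(ds.n_sites):
            col = H[:, j]
            if ds.ploidy == 2:
                gts = "\t".join(
                    f"{col[2 * i]}{sep}{col[2 * i + 1]}" for i in range(n_ind)
                )
            else:
                gts = "\t".join(str(col[i]) for i in range(n_ind))
            fh.write(
                f"{ds.chrom}\t{ds.positions[j]}\t.\t{_ANCESTRAL_BASE}\t"
                f"{_DERIVED_BASE}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path, seq_length_bp: int | None = None) -> HaplotypeDataset:
    """Read a phased VCF into a :class:`HaplotypeDataset`.

    Any non-reference allele is treated as derived. The region length is taken
    from the contig header when present, else from ``seq_length_bp``, else from
    the last variant position.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    chrom = None
    columns: list[np.ndarray] = []
    positions: list[int] = []
    ploidy = None
    for var in vcf:
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("multi-chromosome VCFs are not supported")
        gts = np.asarray(var.genotypes, dtype=np.int64)
        p = gts.shape[1] - 1  # last column is the phased flag
        if ploidy is None:
            ploidy = p
        elif p != ploidy:
            raise ValueError("mixed ploidy in VCF")
        alleles = gts[:, :p]
        if np.any(alleles < 0):
            raise ValueError(f"missing genotypes at position {var.POS}")
        if p == 2 and not np.all(gts[:, 2] == 1):
            raise ValueError(f"unphased genotype at position {var.POS}")
        columns.append((alleles.reshape(-1) > 0).astype(np.uint8))
        positions.append(var.POS)
    if not columns:
        raise ValueError("VCF contains no variant records")
    if seq_length_bp is None:
        seq_length_bp = positions[-1]
        if chrom in vcf.seqnames:
            length = vcf.seqlens[vcf.seqnames.index(chrom)]
            if length > 0:
                seq_length_bp = length
    return HaplotypeDataset(
        haplotypes=np.column_stack(columns),
        positions=np.asarray(positions, dtype=np.int64),
        seq_length_bp=int(seq_length_bp),
        chrom=chrom or "22",
        ploidy=int(ploidy or 2),
    )
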