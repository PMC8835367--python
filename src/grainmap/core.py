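"""Core domain types shared across the pipeline.

The central container is :class:`GenotypeMatrix`, a materials x variants
dosage matrix (alt-allele counts in {0, 1, 2}) with an optional missingness
mask recording which entries were imputed.  Coordinates are 1-based and
inclusive throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Grain-shape trait labels: length, width, length/width ratio,
#: circumference and area (grain size), in mm, mm, ratio, mm and mm^2.
TRAITS = ("GL", "GW", "GLWR", "GC", "GS")

#: SNP consequence classes used for candidate-gene screening.
CONSEQUENCE_CLASSES = ("amino_acid_change", "splicing_change", "promoter", "other")

# IUPAC ambiguity codes for unordered heterozygous base pairs.
IUPAC_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


class GrainmapError(ValueError):
    """Fatal pipeline error (bad input, empty result, degenerate model)."""


def variant_id(chrom: str, pos: int) -> str:
    """Synthesize the conventional ``chr<NN>_<pos>`` variant identifier.

    Numeric chromosome labels are zero-padded to two digits
    (``chr02_34347981``); non-numeric labels are used verbatim.
    """
    label = str(chrom)
    if label.lower().startswith("chr"):
        label = label[3:]
    if label.isdigit():
        return f"chr{int(label):02d}_{pos}"
    return f"{label}_{pos}"


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise GrainmapError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise GrainmapError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if not self.id:
            object.__setattr__(self, "id", variant_id(self.chrom, self.pos))


@dataclass
class GenotypeMatrix:
    """Materials x variants alt-allele dosage matrix.

    ``dosage`` holds imputed values in {0, 1, 2}; ``missing`` (same shape,
    boolean) marks entries that were missing before imputation so that
    haplotype calling can leave those materials unassigned.
    """

    materials: list[str]
    variants: list[Variant]
    dosage: np.ndarray
    missing: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.materials), len(self.variants)):
            raise GrainmapError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.materials)} materials x {len(self.variants)} variants"
            )
        if self.missing is not None and self.missing.shape != self.dosage.shape:
            raise GrainmapError("missing mask shape does not match dosage")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise GrainmapError("variant ids are not unique")
        self._index = {vid: j for j, vid in enumerate(ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_materials(self) -> int:
        return len(self.materials)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants])

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def index_of(self, vid: str) -> int:
        try:
            return self._index[vid]
        except KeyError:
            raise GrainmapError(f"variant {vid!r} not in genotype matrix") from None

    def variant(self, vid: str) -> Variant:
        return self.variants[self.index_of(vid)]

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant (on imputed dosage)."""
        return self.dosage.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, vids: list[str]) -> "GenotypeMatrix":
        idx = [self.index_of(v) for v in vids]
        return GenotypeMatrix(
            materials=list(self.materials),
            variants=[self.variants[j] for j in idx],
            dosage=self.dosage[:, idx].copy(),
            missing=None if self.missing is None else self.missing[:, idx].copy(),
        )

    # -- base calls --------------------------------------------------------
    def base_call(self, material_idx: int, vid: str) -> str | None:
        """Single-letter diploid call: homozygote base, IUPAC heterozygote,
        or ``None`` when the entry was missing before imputation."""
        j = self.index_of(vid)
        if self.missing is not None and self.missing[material_idx, j]:
            return None
        v = self.variants[j]
        d = int(self.dosage[material_idx, j])
        if d == 0:
            return v.ref
        if d == 2:
            return v.alt
        pair = frozenset((v.ref, v.alt))
        try:
            return IUPAC_PAIR[pair]
        except KeyError:
            raise GrainmapError(f"no IUPAC code for allele pair {sorted(pair)} at {vid}") from None

    def chrom_lengths(self) -> dict[str, int]:
        """Chromosome label -> largest observed position (used as a working
        chromosome length when none is supplied)."""
        out: dict[str, int] = {}
        for v in self.variants:
            out[v.chrom] = max(out.get(v.chrom, 0), v.pos)
        return out


@dataclass
class GeneModel:
    """Gene span with strand-aware promoter window and per-SNP consequences.

    ``snp_effects`` maps variant id -> consequence class; variants not in the
    mapping default to ``"other"``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int | None = None
    snp_effects: dict[str, str] = field(default_factory=dict)
    promoter_bp: int = 2000
    annotation: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GrainmapError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise GrainmapError(f"gene {self.gene_id}: start > end")
        if self.tss is None:
            self.tss = self.start if self.strand == "+" else self.end

    def promoter_window(self) -> tuple[int, int]:
        """1-based inclusive promoter span, upstream of the TSS in the
        transcription direction (reflected for minus-strand genes)."""
        if self.strand == "+":
            return (max(1, self.tss - self.promoter_bp), self.tss - 1)
        return (self.tss + 1, self.tss + self.promoter_bp)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_promoter(self, pos: int) -> bool:
        lo, hi = self.promoter_window()
        return lo <= pos <= hi

    def consequence(self, vid: str) -> str:
        return self.snp_effects.get(vid, "other")
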