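"""QTL interval construction, merging, naming and importance filtering.

Every significant SNP spawns the interval [pos - decay, pos + decay]
(decay = LD decay distance, default 125 kb), intervals overlapping or
touching within one trait x environment are merged, detections from
different environments whose merged spans overlap are identified as one QTL,
and QTLs are kept when they meet at least one of four criteria: repeated
detection across environments, overlap with a reported gene, a run of
successive significant member SNPs, or peak PVE >= 10%.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .core import GrainmapError
from .gwas import AssociationRecord

CRITERIA = ("repeated_across_env", "contains_known_gene", "successive_peaks", "pve_ge_threshold")


def snp_interval(pos: int, decay_bp: int, chrom_length: int) -> tuple[int, int]:
    """[pos - decay_bp, pos + decay_bp], clipped to [1, chrom_length]."""
    if decay_bp <= 0:
        raise GrainmapError("decay_bp must be > 0")
    if not (1 <= pos <= chrom_length):
        raise GrainmapError(f"position {pos} outside chromosome of length {chrom_length}")
    return max(1, pos - decay_bp), min(chrom_length, pos + decay_bp)


@dataclass
class QtlDetection:
    """One merged interval for one trait x environment."""

    environment: str
    chrom: str
    start: int
    end: int
    members: list[AssociationRecord]

    @property
    def peak(self) -> AssociationRecord:
        # minimum p; ties broken toward the smaller position
        return min(self.members, key=lambda r: (r.p, r.pos))


@dataclass
class Qtl:
    """A named QTL: the union of per-environment detections whose spans
    overlap, for one trait on one chromosome."""

    name: str
    trait: str
    chrom: str
    start: int
    end: int
    detections: list[QtlDetection]
    known_genes: list[str] = field(default_factory=list)
    flags: dict = field(default_factory=dict)
    criteria: list[str] = field(default_factory=list)

    @property
    def environments(self) -> list[str]:
        return sorted({d.environment for d in self.detections})

    @property
    def peak(self) -> AssociationRecord:
        return min((d.peak for d in self.detections), key=lambda r: (r.p, r.pos))

    @property
    def member_ids(self) -> list[str]:
        return sorted({r.variant_id for d in self.detections for r in d.members})


def merge_intervals(items: list[tuple[int, int, AssociationRecord]]) -> list[tuple[int, int, list[AssociationRecord]]]:
    """Union of overlapping-or-touching intervals on one chromosome (one
    trait x environment).  Touching means next.start <= current.end + 1.
    Idempotent."""
    if not items:
        return []
    items = sorted(items, key=lambda t: (t[0], t[1]))
    merged: list[list] = []
    for start, end, rec in items:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2].extend([rec] if isinstance(rec, AssociationRecord) else rec)
        else:
            merged.append([start, end, [rec] if isinstance(rec, AssociationRecord) else list(rec)])
    return [(s, e, members) for s, e, members in merged]


def detect_qtls(sig_records: list[AssociationRecord], decay_bp: int,
                chrom_lengths: dict[str, int]) -> list[QtlDetection]:
    """Build merged per-environment detections from significant SNPs of one
    trait (all environments, all chromosomes)."""
    detections: list[QtlDetection] = []
    by_env_chrom: dict[tuple[str, str], list] = {}
    for r in sig_records:
        length = chrom_lengths.get(r.chrom)
        if length is None:
            raise GrainmapError(f"no chromosome length for {r.chrom}")
        s, e = snp_interval(r.pos, decay_bp, length)
        by_env_chrom.setdefault((r.environment, r.chrom), []).append((s, e, r))
    for (env, chrom), items in sorted(by_env_chrom.items()):
        for s, e, members in merge_intervals(items):
            detections.append(QtlDetection(environment=env, chrom=chrom, start=s, end=e, members=members))
    return detections


def _chrom_label(chrom: str) -> str:
    label = str(chrom)
    if label.lower().startswith("chr"):
        label = label[3:]
    return str(int(label)) if label.isdigit() else label


def name_qtls(detections: list[QtlDetection], trait: str) -> list[Qtl]:
    """Group cross-environment detections by span overlap and assign names.

    Name = ``q<TRAIT><chrom>`` with an ``.k`` suffix (ascending start) when a
    trait x chromosome carries more than one QTL.  Detections from different
    environments that overlap share one name (cross-environment identity).
    """
    qtls: list[Qtl] = []
    by_chrom: dict[str, list[QtlDetection]] = {}
    for d in detections:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom in sorted(by_chrom):
        dets = sorted(by_chrom[chrom], key=lambda d: (d.start, d.end))
        # sweep-line grouping: overlapping (or touching) spans share an entity
        groups: list[list[QtlDetection]] = []
        cur_end = None
        for d in dets:
            if groups and cur_end is not None and d.start <= cur_end + 1:
                groups[-1].append(d)
                cur_end = max(cur_end, d.end)
            else:
                groups.append([d])
                cur_end = d.end
        label = _chrom_label(chrom)
        for k, grp in enumerate(groups, start=1):
            name = f"q{trait}{label}"
            if len(groups) > 1:
                name += f".{k}"
            qtls.append(Qtl(
                name=name, trait=trait, chrom=chrom,
                start=min(d.start for d in grp), end=max(d.end for d in grp),
                detections=grp,
            ))
    return qtls


def annotate_known_genes(qtls: list[Qtl], known: pd.DataFrame | None) -> list[Qtl]:
    """Flag QTLs whose span strictly overlaps a known gene's span (sharing at
    least one bp; abutting at end + 1 does not count)."""
    for q in qtls:
        q.known_genes = []
        if known is None or known.empty:
            continue
        same = known[known["chrom"].astype(str).map(_chrom_label) == _chrom_label(q.chrom)]
        hit = same[(same["start"] <= q.end) & (same["end"] >= q.start)]
        q.known_genes = sorted(hit["gene_id"].tolist())
    return qtls


def filter_important(qtls: list[Qtl], pve_threshold: float = 10.0,
                     min_peak_run: int = 3) -> list[Qtl]:
    """Keep QTLs meeting at least one importance criterion; each kept QTL's
    ``criteria`` lists which fired.  ``annotate_known_genes`` must have run
    first for the known-gene criterion to be meaningful."""
    kept = []
    for q in qtls:
        q.flags = {
            "repeated_across_env": len(q.environments) >= 2,
            "contains_known_gene": bool(q.known_genes),
            "successive_peaks": max(len(d.members) for d in q.detections) >= min_peak_run,
            "pve_ge_threshold": any(d.peak.pve_pct >= pve_threshold for d in q.detections),
        }
        q.criteria = [c for c in CRITERIA if q.flags[c]]
        if q.criteria:
            kept.append(q)
    return kept


def qtl_table_rows(qtls: list[Qtl]) -> list[dict]:
    """Rows for :func:`grainmap.io.write_association_table` (one row per
    detection, as in the published table)."""
    rows = []
    for q in sorted(qtls, key=lambda q: (q.trait, _chrom_label(q.chrom).rjust(2, "0"), q.start)):
        for d in sorted(q.detections, key=lambda d: d.peak.p):
            pk = d.peak
            rows.append({
                "qtl": q.name, "env": d.environment, "trait": q.trait,
                "chrom": _chrom_label(q.chrom), "start": d.start, "end": d.end,
                "peak_id": pk.variant_id, "ref": pk.ref, "alt": pk.alt,
                "effect": pk.effect, "se": pk.se, "p": pk.p, "pve_pct": pk.pve_pct,
                "criteria": ";".join(q.criteria),
                "known_genes": ";".join(q.known_genes),
                "members": ";".join(r.variant_id for r in d.members),
            })
    return rows


def load_table3() -> pd.DataFrame:
    """Packaged 39-QTL table from the source study (one row per
    QTL x environment detection)."""
    ref = importlib.resources.files("grainmap.data") / "table3.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"CHRO": str})
    df["Cloned_Gene"] = df["Cloned_Gene"].fillna("")
    return df
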