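"""Quadruple-index demultiplexing, cut-site remnant checking, and molecular
ID tag deduplication.

Assignment runs outside-in: the two 8-nt external indexes (I1 = i7,
I2 = i5) resolve the plate / sample group; the variable-length in-line
indexes at the start of R1 and R2 resolve the well.  Because in-line tags
vary in length, a tag candidate counts only when the expected cut-site
remnant follows immediately after it, which makes prefix-sharing tags
unambiguous.  All ambiguity is resolved to *unassigned*, never to an
arbitrary candidate: the published index sets keep a minimum pairwise edit
distance of 3, so a tie implies at least two sequencing errors.

Remnant classification distinguishes the intended first-enzyme remnant from
the blocking (third) enzyme's remnant — loci cut by the third enzyme are
real genomic loci but are usually filtered; their share of reads is the
``third_enzyme_fraction``.  In ``rescue1`` mode a single mismatch to the
intended remnant is rescued, but a third-enzyme call always requires an
exact third remnant so sequencing errors cannot inflate the third-enzyme
fraction.
"""

from __future__ import annotations

import csv
import itertools
import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .adapters import (
    DesignTable,
    IndexTag,
    PlateLayout,
    intended_remnant,
    min_pairwise_edit_distance,
    r2_remnant,
)
from .enzymes import EnzymeRegistry, RestrictionEnzyme

__all__ = [
    "DemuxConfig",
    "DemuxStats",
    "PrimerTable",
    "RemnantSpec",
    "assign_external",
    "assign_internal",
    "check_cutsite",
    "clone_filter",
    "demux_run",
    "third_enzyme_proportion",
]


@dataclass
class DemuxConfig:
    external_mismatch_tol: int = 1
    internal_mismatch_tol: int = 1
    radcheck_mode: str = "exact"  # "exact" | "rescue1" | "disabled"
    trim_tags: bool = True
    umi_mode: bool = False
    umi_key_length: int = 30
    third_enzyme_handling: str = "separate"  # "separate" | "retain"

    def __post_init__(self):
        if not 0 <= self.external_mismatch_tol <= 2:
            raise ValueError("external_mismatch_tol must be 0-2")
        if not 0 <= self.internal_mismatch_tol <= 1:
            raise ValueError("internal_mismatch_tol must be 0-1")
        if self.radcheck_mode not in ("exact", "rescue1", "disabled"):
            raise ValueError(f"unknown radcheck_mode {self.radcheck_mode!r}")
        if self.third_enzyme_handling not in ("separate", "retain"):
            raise ValueError("third_enzyme_handling must be separate|retain")


@dataclass
class RemnantSpec:
    """Expected cut-site remnants for one adapter design / enzyme choice."""

    r1_intended: str
    r1_third: str
    r2_expected: str

    @classmethod
    def from_design(cls, table: DesignTable, registry: EnzymeRegistry,
                    design_id: int, first_enzyme: str, second_enzyme: str,
                    blocking_enzyme: str) -> "RemnantSpec":
        r1d = table.design(design_id, "read1")
        r2d = table.design(design_id, "read2")
        return cls(
            r1_intended=intended_remnant(r1d, registry[first_enzyme]),
            r1_third=intended_remnant(r1d, registry[blocking_enzyme]),
            r2_expected=r2_remnant(r2d, registry[second_enzyme]),
        )


class PrimerTable:
    """iTru5/iTru7 external index table; distance >= 3 within each side."""

    def __init__(self, i5: dict[str, str], i7: dict[str, str],
                 plates: dict[tuple[str, str], str]):
        for side, tags in (("i5", i5), ("i7", i7)):
            if len(tags) >= 2:
                d = min_pairwise_edit_distance(list(tags.values()))
                if d < 3:
                    raise ValueError(
                        f"{side} index set violates minimum edit distance 3 "
                        f"(found {d})"
                    )
        self.i5 = i5
        self.i7 = i7
        self.plates = plates  # (i5_seq, i7_seq) -> plate id

    @classmethod
    def from_csv(cls, path, plate_assignments=None):
        i5, i7 = {}, {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                (i5 if row["side"] == "i5" else i7)[row["name"]] = row["sequence"]
        if plate_assignments is None:
            plates = {(a, b): f"{na}-{nb}"
                      for na, a in i5.items() for nb, b in i7.items()}
        else:
            plates = plate_assignments
        return cls(i5, i7, plates)


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def _best_unique(seq: str, candidates: dict[str, str], tol: int):
    """Name of the unique candidate within ``tol`` mismatches, else None."""
    best, best_d, tied = None, tol + 1, False
    for name, cand in candidates.items():
        d = _hamming(seq, cand)
        if d < best_d:
            best, best_d, tied = name, d, False
        elif d == best_d:
            tied = True
    if best is None or tied:
        return None
    return best


def assign_external(i1: str, i2: str, primers: PrimerTable, tol: int = 1):
    """Resolve (I1=i7, I2=i5) reads to a plate id, or None on miss/tie."""
    i7_name = _best_unique(i1.upper(), primers.i7, tol)
    i5_name = _best_unique(i2.upper(), primers.i5, tol)
    if i7_name is None or i5_name is None:
        return None
    key = (primers.i5[i5_name], primers.i7[i7_name])
    return primers.plates.get(key)


def _remnant_ok(observed: str, spec: RemnantSpec, side: str, mode: str) -> bool:
    if mode == "disabled":
        return True
    if side == "r1":
        if observed == spec.r1_third:
            return True
        if mode == "exact":
            return observed == spec.r1_intended
        return _hamming(observed, spec.r1_intended) <= 1
    if mode == "exact":
        return observed == spec.r2_expected
    return _hamming(observed, spec.r2_expected) <= 1


def assign_internal(r1: str, r2: str, layout: PlateLayout, spec: RemnantSpec,
                    config: DemuxConfig):
    """Resolve the in-line tag pair to a well.

    Variable-length tags are disambiguated by requiring the expected remnant
    (intended or third-enzyme on the R1 side) immediately after the tag.
    Returns ``(well, reason)`` with well None on failure.
    """
    r1u, r2u = r1.upper(), r2.upper()
    tol = config.internal_mismatch_tol
    mode = config.radcheck_mode
    matches = []
    saw_tag = False
    for well, (t1, t2) in layout.wells.items():
        l1, l2 = len(t1.sequence), len(t2.sequence)
        if _hamming(r1u[:l1], t1.sequence) > tol:
            continue
        if _hamming(r2u[:l2], t2.sequence) > tol:
            continue
        saw_tag = True
        if not _remnant_ok(r1u[l1: l1 + len(spec.r1_intended)], spec, "r1", mode):
            continue
        if not _remnant_ok(r2u[l2: l2 + len(spec.r2_expected)], spec, "r2", mode):
            continue
        matches.append(well)
    if len(matches) == 1:
        return matches[0], ""
    if not matches:
        return None, "no cut-site" if saw_tag else "no in-line tag"
    return None, "ambiguous"


def check_cutsite(r1: str, tag: IndexTag, spec: RemnantSpec,
                  mode: str = "exact") -> str:
    """Classify the R1 cut-site remnant after the in-line tag.

    exact: only the intended remnant passes; rescue1: one mismatch to the
    intended remnant is allowed, but an exact third-enzyme remnant always
    classifies as third_enzyme; disabled: exact intended/third matching with
    passthrough (never 'fail').
    """
    observed = r1.upper()[len(tag.sequence): len(tag.sequence) + len(spec.r1_intended)]
    if observed == spec.r1_third:
        return "third_enzyme"
    if observed == spec.r1_intended:
        return "intended"
    if mode == "exact":
        return "fail"
    if mode == "rescue1":
        return "intended" if _hamming(observed, spec.r1_intended) <= 1 else "fail"
    return "intended"  # disabled: left in place, flagged upstream


def clone_filter(records, config: DemuxConfig):
    """Collapse PCR duplicates by (8N tag, R1 prefix, R2 prefix).

    ``records`` yields (read_id, r1_seq, r2_seq, umi_seq) tuples; the first
    record of each key is kept.  Returns (kept, duplicate_fraction).
    """
    k = config.umi_key_length
    seen = set()
    kept = []
    total = 0
    for rec in records:
        read_id, r1, r2, umi = rec
        if umi is None or umi == "":
            raise ValueError("umi_mode requires the I2 (molecular ID tag) stream")
        total += 1
        key = (umi.upper(), r1.upper()[:k], r2.upper()[:k])
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    frac = 0.0 if total == 0 else 1.0 - len(kept) / total
    return kept, frac


@dataclass
class DemuxStats:
    total_reads: int = 0
    per_sample: dict = field(default_factory=dict)  # well -> retained reads
    intended_per_sample: dict = field(default_factory=dict)
    third_per_sample: dict = field(default_factory=dict)
    unassigned: dict = field(default_factory=dict)  # reason -> count
    duplicate_fraction: float | None = None
    normalized_coverage: dict = field(default_factory=dict)

    @property
    def retained(self) -> int:
        return sum(self.per_sample.values())

    @property
    def retained_fraction(self) -> float:
        return self.retained / self.total_reads if self.total_reads else 0.0

    def to_json(self, path=None):
        data = {
            "total_reads": self.total_reads,
            "retained": self.retained,
            "retained_fraction": self.retained_fraction,
            "per_sample": dict(sorted(self.per_sample.items())),
            "third_per_sample": dict(sorted(self.third_per_sample.items())),
            "unassigned": self.unassigned,
            "duplicate_fraction": self.duplicate_fraction,
            "third_enzyme": third_enzyme_proportion(self),
            "normalized_coverage": self.normalized_coverage,
        }
        if path is not None:
            Path(path).write_text(json.dumps(data, indent=2) + "\n")
        return data

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("sample\tretained\tthird_enzyme\tthird_fraction\n")
            props = third_enzyme_proportion(self)["per_sample"]
            for well in sorted(set(self.per_sample) | set(self.third_per_sample)):
                n = self.per_sample.get(well, 0)
                t = self.third_per_sample.get(well, 0)
                p = props.get(well)
                fh.write(f"{well}\t{n}\t{t}\t"
                         f"{'' if p is None else f'{p:.4f}'}\n")


def third_enzyme_proportion(stats: DemuxStats) -> dict:
    """Third-enzyme read share per sample plus pooled mean/sd.

    The proportion is third / (intended + third); samples with no classified
    reads are reported as missing (None).
    """
    per = {}
    for well in sorted(set(stats.intended_per_sample)
                       | set(stats.third_per_sample)):
        third = stats.third_per_sample.get(well, 0)
        intended = stats.intended_per_sample.get(well, 0)
        denom = intended + third
        per[well] = third / denom if denom else None
    values = [v for v in per.values() if v is not None]
    pooled_third = sum(stats.third_per_sample.values())
    pooled_denom = pooled_third + sum(stats.intended_per_sample.values())
    return {
        "per_sample": per,
        "pooled": pooled_third / pooled_denom if pooled_denom else None,
        "mean": statistics.mean(values) if values else None,
        "sd": statistics.stdev(values) if len(values) > 1 else 0.0,
    }


def _read_quads(r1_path, r2_path, i1_path, i2_path):
    streams = [SeqIO.parse(str(p), "fastq")
               for p in (r1_path, r2_path, i1_path, i2_path)]
    sentinel = object()
    for recs in itertools.zip_longest(*streams, fillvalue=sentinel):
        if any(r is sentinel for r in recs):
            raise ValueError("desynchronized FASTQ streams: unequal lengths")
        ids = {r.id for r in recs}
        if len(ids) != 1:
            raise ValueError(f"desynchronized FASTQ streams at {sorted(ids)}")
        yield recs


def demux_run(
    r1_path, r2_path, i1_path, i2_path,
    layout: PlateLayout,
    primers: PrimerTable | None,
    spec: RemnantSpec,
    config: DemuxConfig,
    out_dir,
) -> DemuxStats:
    """Demultiplex four synchronized FASTQ streams into per-sample files.

    Every input read lands in exactly one bin: a sample, the third-enzyme
    bin (``third_enzyme_handling='separate'``), or the unassigned pair
    (reason in the header comment).  Stats are consistent with bin counts
    by construction and checked before returning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stats = DemuxStats()
    handles = {}

    def handle(name):
        if name not in handles:
            handles[name] = (
                open(out_dir / f"{name}_R1.fastq", "w"),
                open(out_dir / f"{name}_R2.fastq", "w"),
            )
        return handles[name]

    def emit(name, rec1, rec2, trim=(0, 0), comment=""):
        h1, h2 = handle(name)
        for h, rec, cut in ((h1, rec1, trim[0]), (h2, rec2, trim[1])):
            seq = str(rec.seq)[cut:]
            qual = "".join(
                chr(q + 33) for q in
                rec.letter_annotations["phred_quality"][cut:])
            tag = f" {comment}" if comment else ""
            h.write(f"@{rec.id}{tag}\n{seq}\n+\n{qual}\n")

    umi_seen: dict[str, set] = {}
    dup_total = dup_unique = 0
    coverage: dict[str, dict] = {}  # well -> locus key -> read count

    def count_locus(well, r1s, cut):
        key = r1s.upper()[cut: cut + 30]
        bucket = coverage.setdefault(well, {})
        bucket[key] = bucket.get(key, 0) + 1

    try:
        for rec1, rec2, reci1, reci2 in _read_quads(
                r1_path, r2_path, i1_path, i2_path):
            stats.total_reads += 1
            r1s, r2s = str(rec1.seq), str(rec2.seq)
            if primers is not None and not config.umi_mode:
                plate = assign_external(str(reci1.seq), str(reci2.seq),
                                        primers, config.external_mismatch_tol)
                if plate is None:
                    stats.unassigned["external-index"] = (
                        stats.unassigned.get("external-index", 0) + 1)
                    emit("unassigned", rec1, rec2, comment="reason=external-index")
                    continue
            elif primers is not None and config.umi_mode:
                # i5 carries the 8N tag; only i7 identifies the pool
                i7_name = _best_unique(str(reci1.seq).upper(), primers.i7,
                                       config.external_mismatch_tol)
                if i7_name is None:
                    stats.unassigned["external-index"] = (
                        stats.unassigned.get("external-index", 0) + 1)
                    emit("unassigned", rec1, rec2, comment="reason=external-index")
                    continue
            well, reason = assign_internal(r1s, r2s, layout, spec, config)
            if well is None:
                stats.unassigned[reason] = stats.unassigned.get(reason, 0) + 1
                emit("unassigned", rec1, rec2, comment=f"reason={reason}")
                continue
            t1, t2 = layout.wells[well]
            cls = check_cutsite(r1s, t1, spec, config.radcheck_mode)
            if cls == "fail":
                stats.unassigned["no cut-site"] = (
                    stats.unassigned.get("no cut-site", 0) + 1)
                emit("unassigned", rec1, rec2, comment="reason=no-cut-site")
                continue
            if config.umi_mode:
                dup_total += 1
                key = (str(reci2.seq).upper(),
                       r1s.upper()[: config.umi_key_length],
                       r2s.upper()[: config.umi_key_length])
                bucket = umi_seen.setdefault(well, set())
                if key in bucket:
                    stats.unassigned["pcr-duplicate"] = (
                        stats.unassigned.get("pcr-duplicate", 0) + 1)
                    emit("unassigned", rec1, rec2, comment="reason=pcr-duplicate")
                    continue
                bucket.add(key)
                dup_unique += 1
            trim = (0, 0)
            if config.trim_tags:
                trim = (len(t1.sequence) + len(spec.r1_intended),
                        len(t2.sequence) + len(spec.r2_expected))
            if cls == "third_enzyme":
                stats.third_per_sample[well] = (
                    stats.third_per_sample.get(well, 0) + 1)
                if config.third_enzyme_handling == "separate":
                    emit(f"{well}_third", rec1, rec2, trim=trim)
                    continue
                stats.per_sample[well] = stats.per_sample.get(well, 0) + 1
                count_locus(well, r1s, trim[0])
                emit(well, rec1, rec2, trim=trim, comment="third-enzyme")
                continue
            stats.intended_per_sample[well] = (
                stats.intended_per_sample.get(well, 0) + 1)
            stats.per_sample[well] = stats.per_sample.get(well, 0) + 1
            count_locus(well, r1s, trim[0])
            emit(well, rec1, rec2, trim=trim)
    finally:
        for h1, h2 in handles.values():
            h1.close()
            h2.close()

    if config.umi_mode and dup_total:
        stats.duplicate_fraction = 1.0 - dup_unique / dup_total
    for well, loci in coverage.items():
        n = stats.per_sample.get(well, 0)
        if loci and n:
            stats.normalized_coverage[well] = (
                statistics.mean(loci.values()) / n)
    if not _partition_consistent(stats, config):
        raise AssertionError("demux bin counts do not partition the input")
    return stats


def _partition_consistent(stats: DemuxStats, config: DemuxConfig) -> bool:
    third_separate = (config.third_enzyme_handling == "separate")
    binned = sum(stats.per_sample.values()) + sum(stats.unassigned.values())
    if third_separate:
        binned += sum(stats.third_per_sample.values())
    return binned == stats.total_reads
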