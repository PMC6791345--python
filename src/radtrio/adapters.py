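"""2RAD/3RAD adapter designs, in-line index sets, and design validation.

Each design pairs a Read-1 adapter stub (named after the set's *blocking*
enzyme, whose site re-forms on adapter self-ligation) with a Read-2 stub.
Oligo strings follow the published template: a constant stub with an index
slot; on the partner strand the slot holds the reverse complement of the
tag.  Only the Read-1 bottom oligo is 5'-phosphorylated (written with a
leading ``/5phos/`` marker); the Read-2 top "dummy" strand ends in five
non-complementary lowercase bases so it cannot prime during PCR.

The bundled index table is a synthetic stand-in for the full published
index sets: it keeps every printed tag at its printed version letter
and fills the remaining versions with tags generated under the published
constraints (6-9 nt, pairwise Levenshtein >= 3, no >=5 bp in-set recognition
site in any assembled adapter, prefix-free).
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .enzymes import (
    EnzymeRegistry,
    FragmentEnd,
    RestrictionEnzyme,
    find_sites,
    iupac_match,
    revcomp,
)

__all__ = [
    "IndexTag",
    "AdapterStubDesign",
    "OligoPair",
    "PlateLayout",
    "DesignTable",
    "load_designs",
    "load_index_tags",
    "build_adapter",
    "simulate_self_ligation",
    "validate_design",
    "min_pairwise_edit_distance",
    "multiplex_capacity",
    "make_plate_layout",
    "intended_remnant",
    "r2_remnant",
]

PHOS = "/5phos/"
MAX_PLAIN_TAG_LEN = 8  # tags longer than this are admitted with a warning


@dataclass(frozen=True)
class IndexTag:
    """An in-line (internal) index: the first bases of R1 or R2 reads."""

    sequence: str
    version: str  # A-H for Read 1, 1-12 for Read 2
    side: str  # "read1" | "read2"

    def __post_init__(self):
        if not self.sequence or set(self.sequence.upper()) - set("ACGT"):
            raise ValueError(f"index tag {self.sequence!r} must be non-empty ACGT")
        if not 5 <= len(self.sequence) <= 9:
            raise ValueError(
                f"index tag {self.sequence!r}: length {len(self.sequence)} outside 5-9"
            )

    def __len__(self):
        return len(self.sequence)

    @property
    def overlong(self) -> bool:
        return len(self.sequence) > MAX_PLAIN_TAG_LEN


@dataclass(frozen=True)
class AdapterStubDesign:
    """Template for one side of one adapter design (index slot left open)."""

    design_id: int
    side: str  # "read1" | "read2"
    adapter_name: str
    enzyme: str  # blocking enzyme for read1, assigned enzyme for read2
    top_prefix: str
    top_suffix: str
    bottom_prefix: str
    bottom_suffix: str
    tail: str = ""  # read2-only: 5-base non-complementary lowercase tail

    @property
    def bottom_phosphorylated(self) -> bool:
        return self.side == "read1"


@dataclass(frozen=True)
class OligoPair:
    """The two synthesized oligos of one indexed adapter (both 5'->3')."""

    top: str
    bottom: str
    bottom_phosphorylated: bool
    name_top: str
    name_bottom: str

    def strip_markers(self):
        return (self.top, self.bottom[len(PHOS):] if
                self.bottom.startswith(PHOS) else self.bottom)


class DesignTable:
    """The four bundled adapter designs plus their index sets."""

    def __init__(self, designs, r1_tags, r2_tags, overrides):
        self.designs = designs  # {(design_id, side): AdapterStubDesign}
        self.r1_tags = r1_tags  # {version: IndexTag}
        self.r2_tags = r2_tags
        self.overrides = overrides  # {(design_id, side, version): IndexTag}

    def design(self, design_id: int, side: str) -> AdapterStubDesign:
        return self.designs[(design_id, side)]

    def design_ids(self):
        return sorted({d for d, _ in self.designs})

    def tag(self, design_id: int, side: str, version: str) -> IndexTag:
        override = self.overrides.get((design_id, side, version))
        if override is not None:
            return override
        table = self.r1_tags if side == "read1" else self.r2_tags
        return table[version]

    def tags(self, design_id: int, side: str) -> list[IndexTag]:
        table = self.r1_tags if side == "read1" else self.r2_tags
        return [self.tag(design_id, side, v) for v in table]


def _data_path(name: str) -> Path:
    return Path(resources.files("radtrio").joinpath(f"data/{name}"))


def load_designs(path: str | Path | None = None) -> dict:
    """Load adapter stub templates (bundled table by default)."""
    path = _data_path("adapter_designs.csv") if path is None else Path(path)
    designs = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            d = AdapterStubDesign(
                design_id=int(row["design_id"]),
                side=row["side"],
                adapter_name=row["adapter_name"],
                enzyme=row["enzyme"],
                top_prefix=row["top_prefix"],
                top_suffix=row["top_suffix"],
                bottom_prefix=row["bottom_prefix"],
                bottom_suffix=row["bottom_suffix"],
                tail=row.get("tail") or "",
            )
            designs[(d.design_id, d.side)] = d
    return designs


def load_index_tags(path: str | Path | None = None):
    """Load the (synthetic stand-in) universal index sets.

    Returns ``(r1_tags, r2_tags, overrides)``; overrides map
    ``(design_id, side, version)`` to a replacement tag (the BamHI
    R2 #5 exception).
    """
    path = _data_path("index_tags_synthetic.csv") if path is None else Path(path)
    r1, r2, overrides = {}, {}, {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            side = "read1" if row["side"] == "r1" else "read2"
            tag = IndexTag(row["tag"], row["version"], side)
            if row.get("design_override"):
                overrides[(int(row["design_override"]), side, tag.version)] = tag
            elif side == "read1":
                r1[tag.version] = tag
            else:
                r2[tag.version] = tag
    return r1, r2, overrides


def load_design_table(designs_path=None, tags_path=None) -> DesignTable:
    r1, r2, overrides = load_index_tags(tags_path)
    return DesignTable(load_designs(designs_path), r1, r2, overrides)


def build_adapter(design: AdapterStubDesign, tag: IndexTag) -> OligoPair:
    """Splice an index tag into a design template.

    Read-1: top carries the tag as sequenced; the phosphorylated bottom
    carries its reverse complement.  Read-2: the bottom (functional) strand
    carries the tag as sequenced; the dummy top carries the reverse
    complement and ends in the lowercase non-complementary tail.
    """
    if tag.side != design.side:
        raise ValueError(
            f"tag {tag.version} is a {tag.side} index; design is {design.side}"
        )
    t = tag.sequence.upper()
    if design.side == "read1":
        top = design.top_prefix + t + design.top_suffix
        bottom = PHOS + design.bottom_prefix + revcomp(t) + design.bottom_suffix
        name_top = f"{design.adapter_name}_stub_{tag.version}"
        name_bottom = f"{design.adapter_name}_RCp_{tag.version}"
    else:
        top = design.top_prefix + revcomp(t) + design.top_suffix + design.tail
        bottom = design.bottom_prefix + t + design.bottom_suffix
        name_top = f"{design.adapter_name}_RC_stub_{tag.version}"
        name_bottom = f"{design.adapter_name}_{tag.version}"
    return OligoPair(top, bottom, design.bottom_phosphorylated, name_top, name_bottom)


def adapter_end(design: AdapterStubDesign, registry: EnzymeRegistry) -> FragmentEnd:
    """The cohesive end presented by an assembled adapter.

    Derived from the design's assigned enzyme: the adapter completes that
    enzyme's cohesive end, so the single-stranded extension equals the
    enzyme's overhang.  Only Read-1 adapters are phosphorylated at the
    extension.
    """
    enz = registry[design.enzyme]
    if enz.overhang_kind == "blunt":
        return FragmentEnd("adapter", None, "", "blunt",
                           phosphorylated=design.side == "read1")
    if design.side == "read1":
        if enz.overhang_kind == "five_prime":
            seq = design.bottom_prefix[: enz.overhang_length]
        else:
            seq = design.top_suffix[-enz.overhang_length:]
    else:
        if enz.overhang_kind == "five_prime":
            seq = design.top_prefix[: enz.overhang_length]
        else:
            seq = design.bottom_suffix[-enz.overhang_length:]
    return FragmentEnd("adapter", None, seq.upper(), enz.overhang_kind,
                       phosphorylated=design.side == "read1")


def intended_remnant(design: AdapterStubDesign, enzyme: RestrictionEnzyme) -> str:
    """Read-1 cut-site remnant: fixed bases between the in-line tag and the
    first genomic base when a fragment cut by ``enzyme`` is ligated.

    Junction arithmetic: adapter top suffix, then the genomic top strand
    resumes at the enzyme's top cut (``motif[cut_top:]``).
    """
    return (design.top_suffix + enzyme.recognition[enzyme.cut_top:]).upper()


def r2_remnant(design: AdapterStubDesign, enzyme: RestrictionEnzyme) -> str:
    """Read-2 remnant: adapter bottom suffix, then the genomic bottom strand
    resumes at the enzyme's bottom cut (revcomp of ``motif[:cut_bottom]``)."""
    return (design.bottom_suffix + revcomp(enzyme.recognition[: enzyme.cut_bottom])).upper()


def simulate_self_ligation(pair_design: AdapterStubDesign, tag: IndexTag,
                           registry: EnzymeRegistry):
    """Self-ligate an adapter head-to-head and scan the junction for sites.

    Returns ``(junction_seq, hits)``: the top-strand sequence across the
    dimer junction and any registry recognition sites found in it.  Read-2
    adapters are unphosphorylated and cannot self-ligate; blunt adapters are
    reported as unable to form a cohesive dimer.
    """
    end = adapter_end(pair_design, registry)
    if not end.phosphorylated:
        return None, {"reason": "unphosphorylated adapter cannot self-ligate"}
    if end.polarity == "blunt" or not end.overhang_seq:
        return None, {"reason": "no dimer possible"}
    pair = build_adapter(pair_design, tag)
    top, bottom = pair.strip_markers()
    # Head-to-head dimer: the partner adapter is rotated 180 degrees, which
    # puts its (phosphorylated) bottom oligo on the top row, 5' end at the
    # nick.  The sealed top row is therefore top1 + bottom2 for both 5' and
    # 3' cohesive ends; the re-created blocking site spans the seam.
    junction = top.upper() + bottom.upper()
    hits = []
    for enz in registry:
        for hit in find_sites(junction, enz, "linear"):
            hits.append(hit)
    return junction, hits


def min_pairwise_edit_distance(tags: Sequence[IndexTag | str]) -> int:
    """Minimum Levenshtein distance over all unordered tag pairs."""
    seqs = [t.sequence if isinstance(t, IndexTag) else str(t) for t in tags]
    if len(seqs) < 2:
        raise ValueError("need at least two tags")
    return min(
        edlib.align(a, b, task="distance")["editDistance"]
        for a, b in itertools.combinations(seqs, 2)
    )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def multiplex_capacity(n_r1: int, n_r2: int, n_i5: int, n_i7: int) -> int:
    """Number of distinguishable samples under quadruple indexing."""
    counts = (n_r1, n_r2, n_i5, n_i7)
    if any(int(c) != c or c < 1 for c in counts):
        raise ValueError(f"all index counts must be positive integers, got {counts}")
    return int(n_r1) * int(n_r2) * int(n_i5) * int(n_i7)


@dataclass(frozen=True)
class Check:
    name: str
    passed: bool
    details: str = ""


def validate_design(table: DesignTable, registry: EnzymeRegistry,
                    design_ids: Iterable[int] | None = None) -> list[Check]:
    """Run the published design-integrity checks; failures are report rows.

    Covered: (a) the R1 self-ligation junction re-creates exactly the set's
    blocking-enzyme site; (b) no index introduces a >=5 bp in-set recognition
    site into its assembled adapter; (c) min pairwise edit distance >= 3
    within each index set; (d) index lengths within 5-9 (warn > 8);
    (e) the Read-2 dummy tail is non-complementary to its partner;
    (f) each adapter's cohesive end matches its assigned enzyme.
    """
    report: list[Check] = []
    ids = list(design_ids) if design_ids is not None else table.design_ids()
    for did in ids:
        r1d, r2d = table.design(did, "read1"), table.design(did, "read2")
        set_r1 = registry.in_set(f"R1.{'ABCD'[did - 1]}")
        set_r2 = registry.in_set(f"R2.{did}")
        blocking = registry.blocking_for(f"R1.{'ABCD'[did - 1]}")
        in_set = [e for e in set_r1 + set_r2 if len(e.recognition) >= 5]

        # (a) dimer junction == blocking site, exactly once at the junction
        tag = table.tags(did, "read1")[0]
        junction, hits = simulate_self_ligation(r1d, tag, registry)
        site_hits = [h for h in hits if h.enzyme == blocking.name] if junction else []
        ok = junction is not None and len(site_hits) == 1
        report.append(Check(
            f"design{did}.r1_dimer_blocking_site",
            ok,
            f"junction contains {len(site_hits)} {blocking.name} site(s)",
        ))

        # (b) indexes do not create in-set sites (>=5 bp motifs)
        for side, design in (("read1", r1d), ("read2", r2d)):
            for t in table.tags(did, side):
                oligos = build_adapter(design, t)
                top, bottom = (s.upper() for s in oligos.strip_markers())
                offenders = sorted({
                    e.name for e in in_set
                    if _contains_motif(top, e.recognition)
                    or _contains_motif(bottom, e.recognition)
                })
                # the design's own cohesive-end context legitimately contains
                # partial sites; only full recognition sites are offenders
                report.append(Check(
                    f"design{did}.{side}.tag{t.version}.no_in_set_site",
                    not offenders,
                    "creates site(s): " + ", ".join(offenders) if offenders else "",
                ))

        # (c) minimum pairwise edit distance within each set
        for side in ("read1", "read2"):
            tags = table.tags(did, side)
            d = min_pairwise_edit_distance(tags)
            report.append(Check(
                f"design{did}.{side}.min_edit_distance",
                d >= 3,
                f"min pairwise Levenshtein = {d}",
            ))

        # (d) index lengths
        for side in ("read1", "read2"):
            for t in table.tags(did, side):
                within = 5 <= len(t) <= 9
                note = "length > 8 nt (admitted with warning)" if t.overlong else ""
                report.append(Check(
                    f"design{did}.{side}.tag{t.version}.length",
                    within, note,
                ))

        # (e) read-2 dummy tail: exactly 5 lowercase bases, non-complementary
        tag2 = table.tags(did, "read2")[0]
        oligos2 = build_adapter(r2d, tag2)
        tail = oligos2.top[-5:]
        duplex_top = oligos2.top[:-5].upper()
        # the dummy's 5' overhang is unpaired; alignment against the bottom
        # strand starts after it
        ov_len = len(adapter_end(r2d, registry).overhang_seq)
        bottom_rc = revcomp(oligos2.bottom.upper())
        pairing_len = len(duplex_top) - ov_len
        continuation = bottom_rc[pairing_len: pairing_len + 5]
        ok_tail = (tail.islower() and len(tail) == 5
                   and duplex_top[ov_len:] == bottom_rc[:pairing_len]
                   and all(a != b for a, b in zip(tail.upper(), continuation)))
        report.append(Check(
            f"design{did}.read2.noncomplementary_tail",
            ok_tail,
            f"tail {tail!r} vs complementary continuation {continuation!r}",
        ))

        # (f) adapter overhang matches the assigned enzyme's cohesive end
        for side, design in (("read1", r1d), ("read2", r2d)):
            enz = registry[design.enzyme]
            end = adapter_end(design, registry)
            ok_end = (end.polarity == enz.overhang_kind
                      and iupac_match(end.overhang_seq, enz.overhang_motif))
            report.append(Check(
                f"design{did}.{side}.overhang_matches_{enz.name}",
                ok_end,
                f"adapter end {end.overhang_seq!r} ({end.polarity}) vs "
                f"{enz.overhang_motif!r} ({enz.overhang_kind})",
            ))
    return report


def _contains_motif(seq: str, motif: str) -> bool:
    m = len(motif)
    return any(iupac_match(seq[i:i + m], motif) for i in range(len(seq) - m + 1))


@dataclass
class PlateLayout:
    """96-well (or sub-plate) mapping of wells to index combinations."""

    wells: dict  # well id "A01" -> (r1 IndexTag, r2 IndexTag)
    external: dict = field(default_factory=dict)  # well -> (i5, i7) 8-nt strings
    design_id: int = 1

    def __post_init__(self):
        seen = {}
        for well, (r1, r2) in self.wells.items():
            key = (r1.sequence, r2.sequence,
                   *(self.external.get(well) or ("", "")))
            if key in seen:
                raise ValueError(
                    f"duplicate index combination in wells {seen[key]} and {well}"
                )
            seen[key] = well

    def __len__(self):
        return len(self.wells)

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["well", "r1_version", "r1_tag", "r2_version", "r2_tag",
                        "i5", "i7"])
            for well in sorted(self.wells):
                r1, r2 = self.wells[well]
                i5, i7 = self.external.get(well, ("", ""))
                w.writerow([well, r1.version, r1.sequence, r2.version,
                            r2.sequence, i5, i7])

    @classmethod
    def from_csv(cls, path, design_id: int = 1):
        wells, external = {}, {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                wells[row["well"]] = (
                    IndexTag(row["r1_tag"], row["r1_version"], "read1"),
                    IndexTag(row["r2_tag"], row["r2_version"], "read2"),
                )
                if row.get("i5") or row.get("i7"):
                    external[row["well"]] = (row["i5"], row["i7"])
        return cls(wells, external, design_id)


def make_plate_layout(table: DesignTable, design_id: int = 1,
                      external: tuple[str, str] | None = None,
                      n_rows: int = 8, n_cols: int = 12) -> PlateLayout:
    """Lay out R1 versions down rows and R2 versions across columns.

    The full design set gives 96 distinct internal pairs; the optional
    ``external`` (i5, i7) pair is applied plate-wide.
    """
    r1_tags = table.tags(design_id, "read1")
    r2_tags = table.tags(design_id, "read2")
    if n_rows > len(r1_tags) or n_cols > len(r2_tags):
        raise ValueError(
            f"requested {n_rows}x{n_cols} plate exceeds available "
            f"{len(r1_tags)} R1 x {len(r2_tags)} R2 versions"
        )
    wells, ext = {}, {}
    for i in range(n_rows):
        for j in range(n_cols):
            well = f"{chr(ord('A') + i)}{j + 1:02d}"
            wells[well] = (r1_tags[i], r2_tags[j])
            if external is not None:
                ext[well] = external
    return PlateLayout(wells, ext, design_id)
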