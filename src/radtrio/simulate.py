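"""Seeded stochastic simulation of 2RAD/3RAD library construction.

The model follows the bench workflow: genomic DNA is digested with two (or
three) enzymes; adapters and fragments then go through alternating
ligation-digestion cycles in which compatible cohesive ends join with a
per-contact efficiency and every *re-created* recognition site spanning a
junction is cleaved with a per-site probability.  Cycling always ends on a
digestion phase.  Surviving constructs are classified, completed into full
library molecules by (index-adding) PCR, size-selected, and sampled into
four synchronized read streams (R1, R2, I1=i7, I2=i5 or the 8N molecular ID
tag).

Only the bottom strand of each construct is amplifiable: the Read-2 dummy
strand is nicked and the Read-1 top strand is short, so a construct needs a
Read-1 adapter at one end and a Read-2 adapter at the other, with both
bottom-strand junctions sealed.  Ligation here models exactly that sealed
bottom strand; the `bottom_strand_complete` flag exists so degenerate
constructs can be represented.

Simplifications (see the methods note): pairwise random end-matching with a
single efficiency parameter instead of ligation kinetics; no circularization
or inverted (head-to-head genomic) joins; uniform substitution errors only;
PCR duplicates are introduced at read sampling rather than by simulating
amplification cycles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .adapters import (
    AdapterStubDesign,
    DesignTable,
    IndexTag,
    adapter_end,
    build_adapter,
    intended_remnant,
    r2_remnant,
)
from .enzymes import (
    EnzymeRegistry,
    FragmentEnd,
    RestrictionEnzyme,
    digest,
    ends_compatible,
    find_sites,
    iupac_match,
    revcomp,
)

__all__ = [
    "Fragment",
    "AdapterPart",
    "Construct",
    "LibraryMolecule",
    "SimulationConfig",
    "ReadQuad",
    "make_synthetic_genome",
    "digestion_ligation_cycle",
    "classify_construct",
    "amplifiable",
    "pcr_amplify",
    "size_select",
    "generate_reads",
    "expected_locus_count",
    "simulate_plate",
]

# Illumina flow-cell grafting sequences and the fixed primer landing pads of
# the full library molecule (top strand left of the R1 stub, bottom strand
# left of the R2 stub).
P5 = "AATGATACGGCGACCACCGAGATCTACAC"
P7 = "CAAGCAGAAGACGGCATACGAGAT"
R1_STUB_TOP_PREFIX = "ACGACGCTCTTCCGATCT"
R1_STUB_BOTTOM_SUFFIX = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"
R2_STUB_BOTTOM_PREFIX = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"
TOP_FLANK = "ACACTCTTTCCCTAC"  # P5+i5+this+R1 stub == iTru5-primed top strand

UMI_LENGTH = 8
DNA = np.array(list("ACGT"))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Fragment:
    """A digestion product: top-strand segment plus its two ends.

    ``top_seq`` spans the top strand between this fragment's top-strand cut
    coordinates, so it includes a 5' overhang at the left end and a 3'
    extension at the right end (and excludes the complementary cases).
    ``origin`` is (record id, start, end), 0-based half-open.
    """

    top_seq: str
    left_end: FragmentEnd
    right_end: FragmentEnd
    origin: tuple = ("seq", 0, 0)
    circular: bool = False

    def __len__(self):
        return len(self.top_seq)

    def _left_pair_offset(self) -> int:
        e = self.left_end
        return len(e.overhang_seq) if e.polarity == "five_prime" else 0

    def _right_trim(self) -> int:
        e = self.right_end
        return len(e.overhang_seq) if e.polarity == "three_prime" else 0

    def bottom_seq(self) -> str:
        """Bottom strand 5'->3' (right to left), including its extensions."""
        top = self.top_seq.upper()
        right_ov = (self.right_end.overhang_seq
                    if self.right_end.polarity == "five_prime" else "")
        left_ext = (self.left_end.overhang_seq
                    if self.left_end.polarity == "three_prime" else "")
        core = top[self._left_pair_offset(): len(top) - self._right_trim()]
        return right_ov + revcomp(core) + left_ext

    def flipped(self) -> "Fragment":
        """The same physical molecule with strands exchanged."""
        return Fragment(
            top_seq=self.bottom_seq(),
            left_end=self.right_end,
            right_end=self.left_end,
            origin=self.origin,
            circular=self.circular,
        )


@dataclass
class AdapterPart:
    """One annealed adapter stub inside a construct."""

    design: AdapterStubDesign
    tag: IndexTag
    end: FragmentEnd

    @property
    def side(self) -> str:
        return self.design.side


@dataclass
class Junction:
    """A sealed joint between two adjacent construct parts."""

    left_end: FragmentEnd
    right_end: FragmentEnd
    duplex: str  # local top-strand sequence across the seam
    seam: int  # index of the seam within ``duplex``


@dataclass
class Construct:
    """An ordered chain of adapters/fragments produced by ligation."""

    parts: list
    junctions: list
    construct_class: str = ""
    bottom_strand_complete: bool = True


@dataclass
class LibraryMolecule:
    """A full, amplifiable library molecule (Read-1 end on the left)."""

    i5_index: str
    i7_index: str
    r1_tag: IndexTag
    r2_tag: IndexTag
    r1_design: AdapterStubDesign
    r2_design: AdapterStubDesign
    r1_remnant: str
    r2_remnant: str
    insert: Fragment
    molecular_id_tag: str | None = None
    sample: str = ""
    construct_class: str = "desired"
    molecule_id: int = 0

    def bottom_core(self) -> str:
        return (R2_STUB_BOTTOM_PREFIX + self.r2_tag.sequence
                + self.r2_design.bottom_suffix
                + self.insert.bottom_seq()
                + self.r1_design.bottom_prefix
                + revcomp(self.r1_tag.sequence)
                + R1_STUB_BOTTOM_SUFFIX)

    def bottom_strand(self) -> str:
        return (P7 + self.i7_index + self.bottom_core()
                + revcomp(self.i5_index) + revcomp(P5))

    def top_strand(self) -> str:
        return revcomp(self.bottom_strand())

    @property
    def total_length(self) -> int:
        return len(P5) + len(P7) + 16 + len(self.bottom_core())


@dataclass
class ReadQuad:
    """The four reads of one cluster plus the simulation-only truth."""

    name: str
    r1_seq: str
    r2_seq: str
    i1_seq: str
    i2_seq: str
    truth: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Tunable parameters of the library-construction simulation."""

    seed: int = 1
    ligation_efficiency: float = 0.95
    recut_probability: float = 0.75
    n_ligation_digestion_cycles: int = 2
    size_center: int = 550
    size_tol: float = 0.10
    read_length: int = 150
    depth: int = 3
    error_rate: float = 0.0
    umi_mode: bool = False

    def __post_init__(self):
        for name in ("ligation_efficiency", "recut_probability", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_ligation_digestion_cycles < 1:
            raise ValueError("need at least one ligation-digestion cycle")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# --------------------------------------------------------------------------
# synthetic genomes
# --------------------------------------------------------------------------

def _random_bases(rng, n: int, gc: float):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(DNA, size=n, p=p)


def _resolve_motif(motif: str, rng) -> str:
    from .enzymes import IUPAC

    return "".join(
        c if c in "ACGT" else rng.choice(sorted(IUPAC[c])) for c in motif.upper()
    )


def make_synthetic_genome(
    length: int,
    gc: float,
    seed: int,
    planted: list[tuple[RestrictionEnzyme, int]] | None = None,
):
    """Random DNA of configurable length/GC with planted recognition sites.

    Returns ``(record, planted_positions, chance_hits)`` where
    ``planted_positions`` maps enzyme name -> sorted 1-based motif starts and
    ``chance_hits`` lists additional sites that arose by chance (they are
    reported, not scrubbed).  Deterministic under ``seed``.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if length < 1000:
        raise ValueError("synthetic genomes are at least 1 kb")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    planted = planted or []
    rng = np.random.default_rng(seed)
    seq = _random_bases(rng, length, gc)

    total_sites = sum(k for _, k in planted)
    max_motif = max((len(e.recognition) for e, _ in planted), default=0)
    if total_sites * (max_motif + 2) > length // 2:
        raise ValueError("infeasible planting density")

    taken: list[tuple[int, int]] = []
    positions: dict[str, list[int]] = {}
    for enz, count in planted:
        m = len(enz.recognition)
        placed = []
        attempts = 0
        while len(placed) < count:
            attempts += 1
            if attempts > 10000 * max(count, 1):
                raise ValueError("infeasible planting density")
            start = int(rng.integers(0, length - m))
            if any(start < b + 1 and start + m + 1 > a for a, b in taken):
                continue
            concrete = _resolve_motif(enz.recognition, rng)
            seq[start: start + m] = list(concrete)
            taken.append((start, start + m))
            placed.append(start + 1)
        positions[enz.name] = sorted(positions.get(enz.name, []) + placed)

    genome = "".join(seq)
    chance = []
    for enz, _ in planted:
        wanted = set(positions[enz.name])
        for hit in find_sites(genome, enz, "linear"):
            if hit.position not in wanted:
                chance.append(hit)
    record = SeqRecord(Seq(genome), id=f"synthetic_{seed}",
                       description=f"length={length} gc={gc:.2f}")
    return record, positions, chance


# --------------------------------------------------------------------------
# ligation-digestion cycling
# --------------------------------------------------------------------------

def _part_left_context(part, width: int = 8) -> str:
    if isinstance(part, Fragment):
        return part.top_seq[:width].upper()
    if part.side == "read1":  # flipped R1 adapter (dimer partner)
        d, t = part.design, part.tag.sequence
        return (d.bottom_prefix + revcomp(t))[:width].upper()
    d, t = part.design, part.tag.sequence  # R2 dummy strand at the seam
    return (d.top_prefix + revcomp(t))[:width].upper()


def _part_right_context(part, width: int = 8) -> str:
    if isinstance(part, Fragment):
        return part.top_seq[-width:].upper()
    if part.side == "read1":
        d, t = part.design, part.tag.sequence
        return (t + d.top_suffix)[-width:].upper()
    raise AssertionError("Read-2 adapters are canonicalized to the right end")


def _free_end(mol: list, side: str) -> FragmentEnd:
    part = mol[0] if side == "L" else mol[-1]
    if isinstance(part, Fragment):
        return part.left_end if side == "L" else part.right_end
    return part.end


def _flip_molecule(mol: list) -> list:
    out = []
    for part in reversed(mol):
        out.append(part.flipped() if isinstance(part, Fragment) else part)
    return out


def _can_ligate(a: FragmentEnd, b: FragmentEnd) -> bool:
    if not ends_compatible(a, b):
        return False
    return a.phosphorylated or b.phosphorylated


class _Molecule:
    """A growing chain of parts with junction records."""

    __slots__ = ("parts", "junctions")

    def __init__(self, parts, junctions=None):
        self.parts = parts
        self.junctions = junctions or []

    def free_sides(self):
        """Sides on which this chain can still ligate.

        A chain's outward adapter stubs are closed; a bare adapter exposes
        its single cohesive end (reported once, as 'L' — it can serve either
        side because a lone part reads the same from both)."""
        if len(self.parts) == 1 and isinstance(self.parts[0], AdapterPart):
            return ["L"]
        sides = []
        for side in ("L", "R"):
            part = self.parts[0] if side == "L" else self.parts[-1]
            if isinstance(part, Fragment):
                end = part.left_end if side == "L" else part.right_end
                if end.kind != "terminal":
                    sides.append(side)
        return sides

    def flipped(self):
        return _Molecule(_flip_molecule(self.parts),
                         list(reversed(self.junctions)))


def _orient(mol: "_Molecule", target: str, other_end: FragmentEnd):
    """Orient ``mol`` so a ligatable free end faces ``target`` ('L'/'R').

    Bare adapters are orientation-free; chains and fragments flip bodily.
    Returns the (possibly flipped) molecule or None if no end fits.
    """
    if len(mol.parts) == 1 and isinstance(mol.parts[0], AdapterPart):
        return mol if _can_ligate(mol.parts[0].end, other_end) else None
    for cand in (mol, mol.flipped()):
        if target in cand.free_sides() and _can_ligate(
                _free_end(cand.parts, target), other_end):
            return cand
    return None


def _join(left: "_Molecule", right: "_Molecule") -> "_Molecule":
    # canonical orientation: a Read-2 stub never opens a chain on the left
    # (flipping both partners describes the same physical molecule)
    last = left.parts[-1]
    if isinstance(last, AdapterPart) and last.side == "read2":
        left, right = right.flipped(), left.flipped()
    le = _free_end(left.parts, "R")
    re = _free_end(right.parts, "L")
    lctx = _part_right_context(left.parts[-1])
    rctx = _part_left_context(right.parts[0])
    junction = Junction(le, re, lctx + rctx, seam=len(lctx))
    return _Molecule(left.parts + right.parts,
                     left.junctions + [junction] + right.junctions)


def _recreated_sites(junction: Junction, enzymes) -> list:
    hits = []
    for enz in enzymes:
        m = len(enz.recognition)
        for hit in find_sites(junction.duplex, enz, "linear"):
            start = hit.position - 1
            if start < junction.seam < start + m:
                hits.append(enz)
                break
    return hits


def digestion_ligation_cycle(
    fragments: list[Fragment],
    r1_adapter: tuple[AdapterStubDesign, IndexTag],
    r2_adapter: tuple[AdapterStubDesign, IndexTag] | None,
    enzymes,
    config: SimulationConfig,
    registry: EnzymeRegistry | None = None,
    rng: np.random.Generator | None = None,
    n_r1: int | None = None,
    n_r2: int | None = None,
) -> list[Construct]:
    """Alternate ligation and digestion phases, ending on digestion.

    ``enzymes`` are the reaction's active restriction enzymes (two or, for
    the dimer-blocking protocol, three).  ``n_r1``/``n_r2`` set the adapter
    molecule counts; the default five-fold excess over fragments keeps
    fragment ends adapter-saturated, as on the bench.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    reg = registry if registry is not None else EnzymeRegistry(list(enzymes))

    def adapter_mols(spec, count):
        if spec is None or count == 0:
            return []
        design, tag = spec
        end = adapter_end(design, reg)
        return [_Molecule([AdapterPart(design, tag, end)]) for _ in range(count)]

    default_n = 5 * len(fragments) + 2
    pool: list[_Molecule] = [_Molecule([f]) for f in fragments]
    pool += adapter_mols(r1_adapter, default_n if n_r1 is None else n_r1)
    pool += adapter_mols(r2_adapter, default_n if n_r2 is None else n_r2)

    for _ in range(config.n_ligation_digestion_cycles):
        # two pairing passes per ligation phase so an insert can pick up
        # both adapters within one temperature cycle
        pool = _pairing_pass(pool, config, rng)
        pool = _pairing_pass(pool, config, rng)
        pool = _digestion_phase(pool, enzymes, config, rng)

    out = []
    for mol in pool:
        construct = Construct(parts=mol.parts, junctions=mol.junctions)
        construct.construct_class = classify_construct(construct, reg)
        out.append(construct)
    return out


def _bucket_key(end: FragmentEnd):
    return (end.polarity, end.overhang_seq.upper())


def _pairing_pass(pool, config, rng):
    """One round of random pairwise end matching.

    Molecules are visited in random order; each joins at most one compatible
    partner per pass, with probability ligation_efficiency per contact.
    Partners are found through an overhang-indexed lookup, so contact odds
    follow the composition of the pool (adapter excess dominates contacts,
    as on the bench).
    """
    order = rng.permutation(len(pool))
    mols = [pool[i] for i in order]
    used = [False] * len(mols)
    # ends bucketed by cohesive-end signature, phosphorylated entries apart
    # so unphosphorylated (Read-2) ends never scan each other
    phos: dict = {}
    unphos: dict = {}
    for j, m in enumerate(mols):
        for side in m.free_sides():
            e = _free_end(m.parts, side)
            bucket = phos if e.phosphorylated else unphos
            bucket.setdefault(_bucket_key(e), []).append(j)

    def candidates(end):
        want = (end.polarity, revcomp(end.overhang_seq).upper())
        pools = [phos] if not end.phosphorylated else [phos, unphos]
        degenerate = set(end.overhang_seq.upper()) - set("ACGT")
        for bucket in pools:
            if degenerate:
                for (pol, ov), lst in bucket.items():
                    if pol == want[0] and iupac_match(ov, want[1]):
                        yield from lst
            else:
                yield from bucket.get(want, [])
                if bucket is phos:  # degenerate partners match concrete ends
                    for (pol, ov), lst in bucket.items():
                        if (pol, ov) != want and pol == want[0] and \
                                iupac_match(ov, want[1]):
                            yield from lst

    out = []
    for i, mol in enumerate(mols):
        if used[i]:
            continue
        used[i] = True
        joined = None
        for side in mol.free_sides():
            end = _free_end(mol.parts, side)
            partner_idx, partner = None, None
            for j in candidates(end):
                if j == i or used[j]:
                    continue
                got = _orient(mols[j], "R" if side == "L" else "L", end)
                if got is not None:
                    partner_idx, partner = j, got
                    break
            if partner_idx is None:
                continue
            used[partner_idx] = True
            if rng.random() < config.ligation_efficiency:
                joined = (_join(partner, mol) if side == "L"
                          else _join(mol, partner))
            else:
                out.append(mols[partner_idx])  # contact failed; both stay
            break
        out.append(joined if joined is not None else mol)
    return out


def _digestion_phase(pool, enzymes, config, rng):
    """Cleave re-created recognition sites at junctions, each independently
    with probability recut_probability."""
    out = []
    for mol in pool:
        cuts = sorted(
            k for k, j in enumerate(mol.junctions)
            if _recreated_sites(j, enzymes)
            and rng.random() < config.recut_probability
        )
        if not cuts:
            out.append(mol)
            continue
        start = 0
        for k in cuts:
            out.append(_Molecule(mol.parts[start: k + 1],
                                 mol.junctions[start: k]))
            start = k + 1
        out.append(_Molecule(mol.parts[start:], mol.junctions[start:]))
    return out


# --------------------------------------------------------------------------
# classification and PCR
# --------------------------------------------------------------------------

def classify_construct(c: Construct, registry: EnzymeRegistry) -> str:
    """Assign the product class of a ligation construct.

    desired: R1 adapter / primary-enzyme junction / insert / Read-2 junction
    / R2 adapter.  third_site_locus: same, but the R1-side fragment end was
    cut by the set's blocking enzyme.  adapter_dimer: adapter-adapter
    junction.  chimera: more than one genomic fragment.  dead: everything
    that cannot amplify (same adapter type at both ends, missing adapters,
    bare parts).
    """
    parts = c.parts
    adapters = [p for p in parts if isinstance(p, AdapterPart)]
    fragments = [p for p in parts if isinstance(p, Fragment)]
    if len(adapters) == 2 and not fragments:
        return "adapter_dimer"
    if len(fragments) > 1:
        return "chimera"
    if len(fragments) == 1 and len(adapters) == 2:
        sides = {a.side for a in adapters}
        if sides != {"read1", "read2"}:
            return "dead"
        if not isinstance(parts[1], Fragment):
            raise ValueError(f"unclassifiable construct topology: {parts!r}")
        frag = parts[1]
        # canonical orientation: R1 adapter leftmost
        if parts[0].side == "read2":
            frag = frag.flipped()
        r1_side_enzyme = frag.left_end.enzyme
        if r1_side_enzyme is None:
            return "dead"
        enz = registry[r1_side_enzyme]
        if enz.is_blocking():
            return "third_site_locus"
        if "read1_primary" in enz.roles:
            return "desired"
        return "dead"
    return "dead"


def amplifiable(c: Construct) -> bool:
    """Only complete-bottom-strand, adapter-flanked inserts amplify."""
    return bool(c.bottom_strand_complete
                and c.construct_class in ("desired", "third_site_locus"))


def _canonical_insert(c: Construct):
    """(r1_part, fragment, r2_part) with the Read-1 adapter on the left."""
    parts = c.parts
    if isinstance(parts[0], AdapterPart) and parts[0].side == "read2":
        parts = list(reversed(parts))
        parts = [p.flipped() if isinstance(p, Fragment) else p for p in parts]
    return parts[0], parts[1], parts[2]


def pcr_amplify(
    constructs: list[Construct],
    i5_index: str,
    i7_index: str,
    config: SimulationConfig,
    registry: EnzymeRegistry,
    rng: np.random.Generator | None = None,
    sample: str = "",
) -> tuple[list[LibraryMolecule], dict]:
    """Complete amplifiable constructs into full library molecules.

    One molecule per amplifiable construct (copy number is handled at read
    sampling).  In ``umi_mode`` the i5 index is replaced by a fresh random
    8N molecular ID tag per template molecule.
    """
    if len(i5_index) != 8 or len(i7_index) != 8:
        raise ValueError("external indexes must be 8 nt")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    molecules, skipped = [], {"dead": 0, "adapter_dimer": 0, "chimera": 0,
                              "nicked": 0}
    for c in constructs:
        if not amplifiable(c):
            if c.construct_class in ("desired", "third_site_locus"):
                skipped["nicked"] += 1
            else:
                skipped[c.construct_class] = skipped.get(c.construct_class, 0) + 1
            continue
        r1p, frag, r2p = _canonical_insert(c)
        left_enz = registry[frag.left_end.enzyme]
        right_enz = registry[frag.right_end.enzyme]
        umi = None
        if config.umi_mode:
            # the 8N molecular ID tag physically occupies the i5 slot
            umi = "".join(rng.choice(DNA, size=UMI_LENGTH))
        molecules.append(LibraryMolecule(
            i5_index=umi if umi is not None else i5_index,
            i7_index=i7_index,
            r1_tag=r1p.tag,
            r2_tag=r2p.tag,
            r1_design=r1p.design,
            r2_design=r2p.design,
            r1_remnant=intended_remnant(r1p.design, left_enz),
            r2_remnant=r2_remnant(r2p.design, right_enz),
            insert=frag,
            molecular_id_tag=umi,
            sample=sample,
            construct_class=c.construct_class,
        ))
    return molecules, skipped


def size_select(molecules, center: int, tol: float):
    """Keep molecules whose total length is within center*(1 +/- tol),
    bounds inclusive."""
    if not 0.0 <= tol < 1.0:
        raise ValueError(f"size tolerance {tol} outside [0, 1)")
    lo, hi = center * (1.0 - tol), center * (1.0 + tol)
    return [m for m in molecules if lo <= m.total_length <= hi]


# --------------------------------------------------------------------------
# read generation
# --------------------------------------------------------------------------

def _apply_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def generate_reads(
    molecules: list[LibraryMolecule],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[ReadQuad]:
    """Sample sequencing clusters from library molecules.

    Each molecule yields ``config.depth`` clusters (its PCR-duplicate
    group).  R1 reads the top strand from the in-line tag; R2 reads the
    bottom strand likewise; I1 returns i7 and I2 returns i5 (or the 8N
    molecular ID tag in umi_mode).  Substitution errors apply to all four
    reads.  Deterministic under the generator state.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    longest_prefix = max(
        (len(m.r1_tag.sequence) + len(m.r1_remnant) for m in molecules),
        default=0,
    )
    if molecules and config.read_length < longest_prefix + 1:
        raise ValueError(
            f"read_length {config.read_length} too short for tag+remnant "
            f"({longest_prefix}+1)"
        )
    quads = []
    for mid, mol in enumerate(molecules):
        top = mol.top_strand()
        bottom = mol.bottom_strand()
        r1_start = len(P5) + 8 + 33
        r2_start = len(P7) + 8 + len(R2_STUB_BOTTOM_PREFIX)
        r1_full = top[r1_start:]
        r2_full = bottom[r2_start:]
        i2 = mol.molecular_id_tag if config.umi_mode else mol.i5_index
        for dup in range(config.depth):
            name = f"radtrio_{mid}_{dup}:{mol.sample}:{mol.construct_class}"
            quads.append(ReadQuad(
                name=name,
                r1_seq=_apply_errors(r1_full[: config.read_length],
                                     config.error_rate, rng),
                r2_seq=_apply_errors(r2_full[: config.read_length],
                                     config.error_rate, rng),
                i1_seq=_apply_errors(mol.i7_index, config.error_rate, rng),
                i2_seq=_apply_errors(i2, config.error_rate, rng),
                truth={
                    "sample": mol.sample,
                    "class": mol.construct_class,
                    "molecule_id": mid,
                    "duplicate_group": f"M{mid}",
                },
            ))
    return quads


def write_fastq_streams(quads, out_dir, prefix="sim"):
    """Write R1/R2/I1/I2 FASTQ files plus the truth-table TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / f"{prefix}_{k}.fastq" for k in ("R1", "R2", "I1", "I2")}
    handles = {k: open(p, "w") for k, p in paths.items()}
    truth_path = out_dir / f"{prefix}_truth.tsv"
    try:
        with open(truth_path, "w") as truth:
            truth.write("read_id\tsample\tclass\tmolecule_id\tduplicate_group\n")
            for q in quads:
                for key, seq in (("R1", q.r1_seq), ("R2", q.r2_seq),
                                 ("I1", q.i1_seq), ("I2", q.i2_seq)):
                    handles[key].write(
                        f"@{q.name}\n{seq}\n+\n{'I' * len(seq)}\n")
                truth.write(
                    f"{q.name}\t{q.truth['sample']}\t{q.truth['class']}\t"
                    f"{q.truth['molecule_id']}\t{q.truth['duplicate_group']}\n")
    finally:
        for h in handles.values():
            h.close()
    paths["truth"] = truth_path
    return paths


# --------------------------------------------------------------------------
# locus-count expectation
# --------------------------------------------------------------------------

def _motif_probability(motif: str, gc: float) -> float:
    from .enzymes import IUPAC

    base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2,
              "C": gc / 2, "G": gc / 2}
    p = 1.0
    for code in motif.upper():
        p *= sum(base_p[b] for b in IUPAC[code])
    return p


def expected_locus_count(genome_length: int, gc: float, enzymes,
                         size_window: tuple[int, int] | None = None) -> float:
    """Expected number of digest fragments in a size window.

    Independent-bases model: each position starts a cut with probability
    equal to its motif probability; inter-cut distances are geometric.  With
    enzymes of both read roles, a locus is a fragment whose ends pair a
    Read-1-set cutter with a Read-2 cutter (either orientation, hence the
    factor 2); with a single role class, every fragment counts.
    """
    if genome_length <= 0:
        return 0.0
    lam1 = sum(_motif_probability(e.recognition, gc) for e in enzymes
               if e.roles & {"read1_primary", "read1_blocking"})
    lam2 = sum(_motif_probability(e.recognition, gc) for e in enzymes
               if "read2" in e.roles)
    if lam1 == 0.0 or lam2 == 0.0:
        lam = lam1 + lam2
        pair_rate, lam_total = lam * lam, lam
    else:
        pair_rate, lam_total = 2.0 * lam1 * lam2, lam1 + lam2
    if lam_total == 0.0:
        return 0.0
    lo, hi = (1, genome_length) if size_window is None else size_window
    lo = max(int(lo), 1)
    hi = min(int(hi), genome_length)
    if hi < lo:
        return 0.0
    q = 1.0 - lam_total
    # sum_{d=lo..hi} q^(d-1) == (q^(lo-1) - q^hi) / (1 - q)
    geom = (q ** (lo - 1) - q ** hi) / lam_total
    return genome_length * pair_rate * geom


# --------------------------------------------------------------------------
# plate-scale simulation
# --------------------------------------------------------------------------

def _well_genome(rng, n_loci, third_fraction, insert_range, first, second,
                 blocking, filler=1500):
    """Concatenated locus cassettes: (first|blocking) site ... second site.

    Returns (sequence, n_third_planted).  Filler stretches keep non-cassette
    fragments far outside the size window; chance recognition sites outside
    the planted spans are mutated away so the planted locus and third-enzyme
    counts are exact.
    """
    pieces, spans = [], []
    pos = 0

    def add(piece, planted=False):
        nonlocal pos
        pieces.append(piece)
        if planted:
            spans.append((pos, pos + len(piece)))
        pos += len(piece)

    n_third = 0
    for _ in range(n_loci):
        use_third = rng.random() < third_fraction
        left = blocking if use_third else first
        n_third += int(use_third)
        insert = int(rng.integers(insert_range[0], insert_range[1] + 1))
        add("".join(rng.choice(DNA, size=filler)))
        add(_resolve_motif(left.recognition, rng), planted=True)
        add("".join(rng.choice(DNA, size=insert - len(left.recognition))))
        add(_resolve_motif(second.recognition, rng), planted=True)
    add("".join(rng.choice(DNA, size=filler)))
    genome = _scrub_sites("".join(pieces), [first, second, blocking], spans)
    return genome, n_third


def _scrub_sites(seq: str, enzymes, keep_spans, max_rounds: int = 8) -> str:
    """Mutate chance recognition sites outside the planted spans."""
    arr = list(seq)
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for _ in range(max_rounds):
        dirty = False
        for enz in enzymes:
            m = len(enz.recognition)
            for hit in find_sites("".join(arr), enz, "linear"):
                s = hit.position - 1
                if any(a <= s and s + m <= b for a, b in keep_spans):
                    continue
                arr[s + m // 2] = flip[arr[s + m // 2]]
                dirty = True
        if not dirty:
            return "".join(arr)
    raise RuntimeError("could not scrub chance sites from synthetic template")


def simulate_plate(
    table: DesignTable,
    registry: EnzymeRegistry,
    layout,
    config: SimulationConfig,
    n_loci_per_sample: int = 48,
    third_fraction: float = 0.2,
    insert_range: tuple[int, int] = (380, 430),
    first_enzyme: str = "XbaI",
    second_enzyme: str = "EcoRI-HF",
    blocking_enzyme: str = "NheI",
    adapter_excess: int = 20,
):
    """End-to-end seeded simulation of one adapter plate.

    For every well of ``layout``: build a synthetic multi-locus template
    whose loci are bounded by the first (or, at ``third_fraction``, the
    blocking) enzyme on the Read-1 side and the second enzyme on the Read-2
    side; digest; run ligation-digestion cycling; amplify; size-select.
    Returns ``(molecules, truth)`` where truth records planted per-well
    counts.
    """
    first = registry[first_enzyme]
    second = registry[second_enzyme]
    blocking = registry[blocking_enzyme]
    enzymes = [first, second, blocking]
    rng = np.random.default_rng(config.seed)
    molecules = []
    truth = {"wells": {}, "n_third_planted": 0, "n_loci_planted": 0}
    for well in sorted(layout.wells):
        r1_tag, r2_tag = layout.wells[well]
        i5, i7 = layout.external.get(well, ("ACACACAC", "GTGTGTGT"))
        genome, n_third = _well_genome(
            rng, n_loci_per_sample, third_fraction, insert_range,
            first, second, blocking)
        fragments = digest(genome, enzymes, "linear", record_id=well)
        n_adapters = adapter_excess * len(fragments)
        constructs = digestion_ligation_cycle(
            fragments,
            (table.design(layout.design_id, "read1"), r1_tag),
            (table.design(layout.design_id, "read2"), r2_tag),
            enzymes, config, registry=registry, rng=rng,
            n_r1=n_adapters, n_r2=n_adapters)
        mols, _ = pcr_amplify(constructs, i5, i7, config, registry,
                              rng=rng, sample=well)
        mols = size_select(mols, config.size_center, config.size_tol)
        molecules.extend(mols)
        truth["wells"][well] = {
            "n_loci": n_loci_per_sample,
            "n_third_planted": n_third,
            "n_molecules": len(mols),
            "n_third_molecules": sum(
                m.construct_class == "third_site_locus" for m in mols),
        }
        truth["n_third_planted"] += n_third
        truth["n_loci_planted"] += n_loci_per_sample
    for i, m in enumerate(molecules):
        m.molecule_id = i
    return molecules, truth
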