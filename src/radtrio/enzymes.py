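"""Restriction-enzyme registry, IUPAC site finding, and multi-enzyme digestion.

The registry encodes the 2RAD/3RAD enzyme panel: four Read-1 adapter sets
(R1.A-R1.D) and four Read-2 sets (R2.1-R2.4).  Within each Read-1 set one
enzyme is the *blocking* (third) enzyme: its recognition site is re-created
when the Read-1 adapter self-ligates, so adapter-dimers are cleaved during
digestion-ligation cycling.  The remaining Read-1 enzymes are the *primary*
cutters that leave a cohesive end compatible with the set's adapter.

Cut geometry convention: ``cut_top`` / ``cut_bottom`` are base offsets of the
top/bottom strand cuts from the first base of the recognition motif.
``cut_top < cut_bottom`` encodes a 5' overhang, ``>`` a 3' overhang, equality
a blunt cut.  Site positions are reported 1-based at the first motif base on
the top strand.
"""

from __future__ import annotations

import functools
import itertools
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RestrictionEnzyme",
    "SiteHit",
    "FragmentEnd",
    "EnzymeRegistry",
    "load_registry",
    "bundled_registry_path",
    "find_sites",
    "digest",
    "ends_compatible",
    "enumerate_enzyme_combinations",
    "revcomp",
    "iupac_match",
    "RegistryError",
    "DigestError",
]

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class RegistryError(ValueError):
    """Malformed or inconsistent enzyme registry input."""


class DigestError(ValueError):
    """Digestion cannot be resolved (e.g. intersecting cut intervals)."""


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (case preserved)."""
    lower = [i for i, c in enumerate(seq) if c.islower()]
    out = seq.upper().translate(_COMPLEMENT)[::-1]
    if lower:
        n = len(seq)
        chars = list(out)
        for i in lower:
            j = n - 1 - i
            chars[j] = chars[j].lower()
        out = "".join(chars)
    return out


def iupac_match(window: str, motif: str) -> bool:
    """True if ``window`` (concrete or degenerate) satisfies ``motif``.

    Degenerate codes in the window are accepted when their base set is a
    subset of the motif code's base set (an N in an adapter slot matches any
    motif position).
    """
    if len(window) != len(motif):
        return False
    for w, m in zip(window.upper(), motif.upper()):
        allowed = IUPAC.get(m)
        have = IUPAC.get(w)
        if allowed is None or have is None:
            return False
        if not (have <= allowed or allowed <= have):
            return False
    return True


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type-II restriction enzyme and its 2RAD/3RAD bookkeeping."""

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int
    incubation_temp: float
    buffer_activity: dict = field(default_factory=dict, compare=False)
    methylation_sensitive: str = "-"
    roles: frozenset = frozenset()
    design_set: str = ""
    warning: str = ""

    def __post_init__(self):
        if not self.recognition or any(
            c not in IUPAC for c in self.recognition.upper()
        ):
            raise RegistryError(
                f"{self.name}: recognition {self.recognition!r} is not IUPAC DNA"
            )
        for v in self.buffer_activity.values():
            if not 0 <= v <= 100:
                raise RegistryError(f"{self.name}: buffer activity {v} outside [0, 100]")
        if not (0 <= self.cut_top <= len(self.recognition)
                and 0 <= self.cut_bottom <= len(self.recognition)):
            raise RegistryError(f"{self.name}: cut offsets outside the motif")

    @property
    def overhang_length(self) -> int:
        return abs(self.cut_top - self.cut_bottom)

    @property
    def overhang_kind(self) -> str:
        if self.cut_top < self.cut_bottom:
            return "five_prime"
        if self.cut_top > self.cut_bottom:
            return "three_prime"
        return "blunt"

    @property
    def overhang_motif(self) -> str:
        """Single-stranded extension in top-strand coordinates (may be degenerate)."""
        lo, hi = sorted((self.cut_top, self.cut_bottom))
        return self.recognition[lo:hi]

    @property
    def base_name(self) -> str:
        """Enzyme name with a high-fidelity (-HF) suffix stripped."""
        return self.name[:-3] if self.name.endswith("-HF") else self.name

    def is_blocking(self) -> bool:
        return "read1_blocking" in self.roles


@dataclass(frozen=True)
class SiteHit:
    """One recognition-motif match on the top strand (1-based position)."""

    position: int
    matched_seq: str
    enzyme: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("SiteHit.position is 1-based and must be >= 1")


@dataclass(frozen=True)
class FragmentEnd:
    """One extremity of a digestion fragment.

    ``overhang_seq`` is the single-stranded extension sticking out of *this*
    fragment, written 5'->3' along its own strand; empty for blunt and
    terminal ends.
    """

    kind: str  # "terminal" | "cut" | "adapter"
    enzyme: str | None = None
    overhang_seq: str = ""
    polarity: str = "blunt"  # "five_prime" | "three_prime" | "blunt"
    phosphorylated: bool = True

    def __post_init__(self):
        if self.kind == "terminal" and (self.enzyme or self.overhang_seq):
            raise ValueError("terminal ends carry no enzyme or overhang")


class EnzymeRegistry:
    """Ordered collection of :class:`RestrictionEnzyme` with name lookup."""

    def __init__(self, enzymes: Sequence[RestrictionEnzyme]):
        self._enzymes = list(enzymes)
        self._by_name = {}
        for e in self._enzymes:
            if e.name in self._by_name:
                raise RegistryError(f"duplicate enzyme name {e.name!r}")
            self._by_name[e.name] = e

    def __iter__(self):
        return iter(self._enzymes)

    def __len__(self):
        return len(self._enzymes)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> RestrictionEnzyme:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"enzyme {name!r} not in registry") from None

    def with_roles(self, role: str) -> list[RestrictionEnzyme]:
        return [e for e in self._enzymes if role in e.roles]

    def in_set(self, design_set: str) -> list[RestrictionEnzyme]:
        return [e for e in self._enzymes if e.design_set == design_set]

    def blocking_for(self, design_set: str) -> RestrictionEnzyme | None:
        for e in self.in_set(design_set):
            if e.is_blocking():
                return e
        return None


def bundled_registry_path() -> Path:
    return Path(resources.files("radtrio").joinpath("data/enzymes.tsv"))


_COLUMNS = [
    "name", "recognition", "cut_top", "cut_bottom", "temp_C",
    "buf_2_1", "buf_3_1", "buf_cutsmart", "meth_sensitive", "role",
    "design_set",
]


def load_registry(path: str | Path | None = None) -> EnzymeRegistry:
    """Load a tab-separated enzyme registry (bundled panel by default)."""
    path = bundled_registry_path() if path is None else Path(path)
    if not path.exists():
        raise RegistryError(f"registry file not found: {path}")
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        raise RegistryError(f"{path}: empty registry file")
    header = lines[0].rstrip("\n").split("\t")
    if header[: len(_COLUMNS)] != _COLUMNS:
        raise RegistryError(f"{path}: unexpected header {header!r}")
    enzymes = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < len(_COLUMNS):
            raise RegistryError(f"{path}:{lineno}: expected >= {len(_COLUMNS)} columns")
        row = dict(zip(header, fields))
        try:
            enz = RestrictionEnzyme(
                name=row["name"],
                recognition=row["recognition"].upper(),
                cut_top=int(row["cut_top"]),
                cut_bottom=int(row["cut_bottom"]),
                incubation_temp=float(row["temp_C"]),
                buffer_activity={
                    "NEB 2.1": float(row["buf_2_1"]),
                    "NEB 3.1": float(row["buf_3_1"]),
                    "CutSmart": float(row["buf_cutsmart"]),
                },
                methylation_sensitive=row["meth_sensitive"],
                roles=frozenset(row["role"].split("|")),
                design_set=row["design_set"],
                warning=row.get("warning", "") or "",
            )
        except (KeyError, ValueError) as exc:
            raise RegistryError(f"{path}:{lineno}: {exc}") from exc
        if enz.warning:
            warnings.warn(f"{enz.name}: {enz.warning}", stacklevel=2)
        enzymes.append(enz)
    return EnzymeRegistry(enzymes)


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set(IUPAC)
    if bad:
        raise ValueError(f"sequence contains non-IUPAC characters: {sorted(bad)}")
    return seq


def find_sites(
    seq: str,
    enzyme: RestrictionEnzyme,
    topology: str = "linear",
) -> list[SiteHit]:
    """All top-strand matches of the enzyme's recognition motif.

    Circular topology also reports motifs spanning the origin (the scan is
    extended by motif_length - 1 wrapped bases); positions stay within
    1..len(seq).
    """
    if not seq:
        raise ValueError("empty sequence")
    if topology not in ("linear", "circular"):
        raise ValueError(f"unknown topology {topology!r}")
    seq = _validate_sequence(seq)
    motif = enzyme.recognition.upper()
    m = len(motif)
    scan = seq + seq[: m - 1] if topology == "circular" else seq
    limit = len(seq) if topology == "circular" else len(seq) - m + 1
    hits = []
    if set(scan) <= set("ACGT"):
        # concrete input: overlapping regex scan
        pattern = _motif_regex(motif)
        for match in pattern.finditer(scan):
            i = match.start()
            if i < limit:
                hits.append(SiteHit(position=i + 1, matched_seq=scan[i: i + m],
                                    enzyme=enzyme.name))
    else:
        # degenerate input (adapter slots etc.): subset-aware IUPAC matching
        for i in range(max(limit, 0)):
            window = scan[i: i + m]
            if iupac_match(window, motif):
                hits.append(SiteHit(position=i + 1, matched_seq=window,
                                    enzyme=enzyme.name))
    return hits


@functools.lru_cache(maxsize=256)
def _motif_regex(motif: str):
    parts = []
    for code in motif:
        bases = sorted(IUPAC[code])
        parts.append(bases[0] if len(bases) == 1 else f"[{''.join(bases)}]")
    return re.compile(f"(?=({''.join(parts)}))")


def _cut_positions(
    seq: str,
    enzymes: Sequence[RestrictionEnzyme],
    topology: str,
) -> list[tuple[int, int, RestrictionEnzyme, str]]:
    """Sorted (top_cut, bottom_cut, enzyme, matched_seq) tuples, 0-based cuts."""
    n = len(seq)
    cuts = []
    for enz in enzymes:
        for hit in find_sites(seq, enz, topology):
            s = hit.position - 1
            ct, cb = s + enz.cut_top, s + enz.cut_bottom
            if topology == "linear" and not (0 < min(ct, cb) and max(ct, cb) < n):
                continue  # cut would fall outside the molecule
            cuts.append((ct % n if topology == "circular" else ct,
                         cb % n if topology == "circular" else cb,
                         enz, hit.matched_seq))
    cuts.sort(key=lambda c: (min(c[0], c[1]), c[2].name))
    # reject intersecting cut intervals from distinct sites
    spans = sorted((min(ct, cb), max(ct, cb), enz.name)
                   for ct, cb, enz, _ in cuts)
    for (a0, a1, na), (b0, b1, nb) in zip(spans, spans[1:]):
        if b0 < a1 and (a0, a1) != (b0, b1):
            raise DigestError(
                f"intersecting cut intervals: {na} [{a0},{a1}] vs {nb} [{b0},{b1}]"
            )
    # identical double-cuts at the same interval are collapsed
    seen, uniq = set(), []
    for c in cuts:
        key = (c[0], c[1])
        if key not in seen:
            seen.add(key)
            uniq.append(c)
    return uniq


def _ends_for_cut(ct, cb, enz, matched):
    """(right-end-of-left-fragment, left-end-of-right-fragment) for one cut."""
    # overhang in top-strand coordinates, resolved on the actual site
    lo, hi = sorted((enz.cut_top, enz.cut_bottom))
    resolved = matched[lo:hi]
    if enz.overhang_kind == "five_prime":
        left = FragmentEnd("cut", enz.name, revcomp(resolved), "five_prime")
        right = FragmentEnd("cut", enz.name, resolved, "five_prime")
    elif enz.overhang_kind == "three_prime":
        left = FragmentEnd("cut", enz.name, resolved, "three_prime")
        right = FragmentEnd("cut", enz.name, revcomp(resolved), "three_prime")
    else:
        left = FragmentEnd("cut", enz.name, "", "blunt")
        right = FragmentEnd("cut", enz.name, "", "blunt")
    return left, right


def digest(
    seq: str,
    enzymes: Sequence[RestrictionEnzyme],
    topology: str = "linear",
    record_id: str = "seq",
):
    """Cut a sequence with one or more enzymes.

    Returns fragments ordered along the top strand.  Fragments are split at
    top-strand cut coordinates, so concatenating their top strands (each
    overhang counted once) reconstructs the input.  A linear molecule with k
    cuts yields k+1 fragments; a circular one yields k (or one uncut circle).
    """
    from .simulate import Fragment  # Fragment lives with the simulation types

    if not enzymes:
        raise ValueError("at least one enzyme required")
    seq = _validate_sequence(seq)
    n = len(seq)
    cuts = _cut_positions(seq, enzymes, topology)

    terminal = FragmentEnd("terminal")
    if not cuts:
        if topology == "circular":
            return [Fragment(top_seq=seq, left_end=terminal, right_end=terminal,
                             origin=(record_id, 0, n), circular=True)]
        return [Fragment(top_seq=seq, left_end=terminal, right_end=terminal,
                         origin=(record_id, 0, n))]

    fragments = []
    if topology == "linear":
        bounds = [0] + [ct for ct, _, _, _ in cuts] + [n]
        left_ends = [terminal] + [_ends_for_cut(*c)[1] for c in cuts]
        right_ends = [_ends_for_cut(*c)[0] for c in cuts] + [terminal]
        for i in range(len(cuts) + 1):
            fragments.append(Fragment(
                top_seq=seq[bounds[i]: bounds[i + 1]],
                left_end=left_ends[i], right_end=right_ends[i],
                origin=(record_id, bounds[i], bounds[i + 1]),
            ))
    else:
        k = len(cuts)
        for i in range(k):
            ct0 = cuts[i][0]
            ct1 = cuts[(i + 1) % k][0]
            top = seq[ct0:ct1] if ct1 > ct0 else seq[ct0:] + seq[:ct1]
            fragments.append(Fragment(
                top_seq=top,
                left_end=_ends_for_cut(*cuts[i])[1],
                right_end=_ends_for_cut(*cuts[(i + 1) % k])[0],
                origin=(record_id, ct0, ct1),
            ))
    return fragments


def ends_compatible(a: FragmentEnd, b: FragmentEnd) -> bool:
    """True iff two ends can ligate: same polarity, reverse-complementary
    single-stranded extensions (blunt-blunt is compatible)."""
    if a.kind == "terminal" or b.kind == "terminal":
        return False
    if a.polarity != b.polarity:
        return False
    if a.polarity == "blunt":
        return True
    if len(a.overhang_seq) != len(b.overhang_seq):
        return False
    return iupac_match(a.overhang_seq, revcomp(b.overhang_seq))


def enumerate_enzyme_combinations(registry: EnzymeRegistry):
    """All usable (read1_enzyme, read2_enzyme, blocking_enzyme) combinations.

    High-fidelity variants collapse onto their parent enzyme; blunt Read-2
    entries (no cohesive end to match a sticky adapter) are excluded.  Every
    Read-1 primary couples with the blocking enzyme of its own adapter set.
    """
    primaries, seen = [], set()
    for e in registry.with_roles("read1_primary"):
        if e.base_name in seen:
            continue
        seen.add(e.base_name)
        primaries.append(e)
    read2, seen2 = [], set()
    for e in registry.with_roles("read2"):
        if e.base_name in seen2 or e.overhang_kind == "blunt":
            continue
        seen2.add(e.base_name)
        read2.append(e)

    combos = []
    for r1, r2 in itertools.product(primaries, read2):
        blocker = registry.blocking_for(r1.design_set)
        # cohesive ends of the pair must be unique (incompatible)
        if (r1.overhang_kind == r2.overhang_kind
                and len(r1.overhang_motif) == len(r2.overhang_motif)
                and iupac_match(r1.overhang_motif, revcomp(r2.overhang_motif))):
            continue
        combos.append((r1, r2, blocker))
    return combos
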