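"""Demultiplexing, remnant classification, and duplicate removal."""

from collections import Counter

import pytest

from radtrio.adapters import IndexTag, PlateLayout
from radtrio.demux import (
    DemuxConfig,
    PrimerTable,
    RemnantSpec,
    assign_external,
    assign_internal,
    check_cutsite,
    clone_filter,
    demux_run,
    third_enzyme_proportion,
)
from radtrio.simulate import SimulationConfig, generate_reads, simulate_plate, \
    write_fastq_streams


@pytest.fixture(scope="module")
def primers():
    i5 = {"iTru5_01": "ACACACAC", "iTru5_02": "GTGTCTCT"}
    i7 = {"iTru7_01": "GTGTGTGT", "iTru7_02": "ACAGAGAG"}
    plates = {(a, b): f"{na}-{nb}" for na, a in i5.items()
              for nb, b in i7.items()}
    return PrimerTable(i5, i7, plates)


# ------------------------------------------------------------ external index

def test_assign_external_exact_and_one_mismatch(primers):
    assert assign_external("GTGTGTGT", "ACACACAC", primers, 1) \
        == "iTru5_01-iTru7_01"
    assert assign_external("GTGTGTGA", "ACACACAC", primers, 1) \
        == "iTru5_01-iTru7_01"
    assert assign_external("GTGTGTGA", "ACACACAC", primers, 0) is None


def test_assign_external_tie_goes_unassigned():
    i5 = {"a": "AAAAAAAA", "b": "AAAATTTT"}  # distance 4: ties possible
    i7 = {"c": "CCCCCCCC"}
    primers = PrimerTable(i5, i7, {(v, "CCCCCCCC"): k for k, v in i5.items()})
    assert assign_external("CCCCCCCC", "AAAATTTA", primers, 2) == "b"
    # two errors leave the read equidistant from both -> unassigned
    assert assign_external("CCCCCCCC", "AAAATTAA", primers, 2) is None


def test_primer_table_enforces_distance_three():
    with pytest.raises(ValueError, match="edit distance"):
        PrimerTable({"a": "AAAAAAAA", "b": "AAAAAAAT"}, {}, {})


# ------------------------------------------------------------ internal index

def _layout_of(tags):
    wells = {}
    for i, (t1, t2) in enumerate(tags):
        wells[f"W{i}"] = (IndexTag(t1, f"r{i}", "read1"),
                          IndexTag(t2, f"q{i}", "read2"))
    return PlateLayout(wells)


@pytest.fixture(scope="module")
def spec1(design1_spec):
    return design1_spec


def test_assign_internal_resolves_wells_and_reasons(spec1):
    layout = _layout_of([("CCGAAT", "CTAACG"), ("GCGGTA", "ACAGACC")])
    cfg = DemuxConfig()
    genomic = "TTTTGGGGCCCCAAAATTTT"
    r1 = "CCGAAT" + "GCTAGA" + genomic
    r2 = "CTAACG" + "TAATTC" + genomic
    assert assign_internal(r1, r2, layout, spec1, cfg) == ("W0", "")

    no_rem = "CCGAAT" + "GCAAGA" + genomic
    well, reason = assign_internal(no_rem, r2, layout, spec1, cfg)
    assert well is None and reason == "no cut-site"

    well, reason = assign_internal("T" * 40, "T" * 40, layout, spec1, cfg)
    assert well is None and reason == "no in-line tag"


def test_prefix_sharing_tags_disambiguated_by_remnant_position(spec1):
    """One tag is a strict prefix of the other; the remnant anchor after the
    tag picks the right well."""
    layout = _layout_of([("ACGTAC", "CTAACG"), ("ACGTACGCT", "ACAGACC")])
    cfg = DemuxConfig(internal_mismatch_tol=0)
    genomic = "TTTTGGGGCCCCAAAATTTT"
    for t1, t2, well in (("ACGTAC", "CTAACG", "W0"),
                         ("ACGTACGCT", "ACAGACC", "W1")):
        r1 = t1 + "GCTAGA" + genomic
        r2 = t2 + "TAATTC" + genomic
        assert assign_internal(r1, r2, layout, spec1, cfg) == (well, "")


def test_assign_internal_third_remnant_still_assigns(spec1):
    layout = _layout_of([("CCGAAT", "CTAACG")])
    r1 = "CCGAAT" + "GCTAGC" + "T" * 20  # blocking-enzyme remnant
    r2 = "CTAACG" + "TAATTC" + "T" * 20
    assert assign_internal(r1, r2, layout, spec1, DemuxConfig()) == ("W0", "")


# ----------------------------------------------------------------- cut-site

def test_check_cutsite_modes(spec1):
    tag = IndexTag("CCGAAT", "A", "read1")
    mk = lambda rem: "CCGAAT" + rem + "T" * 30  # noqa: E731
    assert check_cutsite(mk("GCTAGA"), tag, spec1, "exact") == "intended"
    assert check_cutsite(mk("GCTAGC"), tag, spec1, "exact") == "third_enzyme"
    assert check_cutsite(mk("GCTGGA"), tag, spec1, "exact") == "fail"
    # rescue1: one mismatch to the intended remnant is rescued ...
    assert check_cutsite(mk("GCTGGA"), tag, spec1, "rescue1") == "intended"
    assert check_cutsite(mk("GCGGGA"), tag, spec1, "rescue1") == "fail"
    # ... but an exact third remnant always wins
    assert check_cutsite(mk("GCTAGC"), tag, spec1, "rescue1") == "third_enzyme"
    # disabled: passthrough, never fail
    assert check_cutsite(mk("TTTTTT"), tag, spec1, "disabled") == "intended"
    assert check_cutsite(mk("GCTAGC"), tag, spec1, "disabled") == "third_enzyme"


# -------------------------------------------------------------- clone_filter

def test_clone_filter_collapses_planted_multiplicity():
    records = []
    for mol in range(40):
        umi = f"{mol:08d}".replace("0", "A").replace("1", "C") \
            .replace("2", "G").replace("3", "T").replace("4", "A") \
            .replace("5", "C").replace("6", "G").replace("7", "T") \
            .replace("8", "A").replace("9", "C")
        for dup in range(3):
            records.append((f"m{mol}d{dup}", "ACGT" * 20 + str(mol) * 0,
                            "TGCA" * 20, umi))
    # identical R1/R2 prefixes force the key onto the tag alone: make them
    # molecule-specific instead
    records = [(rid, f"{rid.split('d')[0]:*<40}" + r1, r2, umi)
               for rid, r1, r2, umi in records]
    kept, frac = clone_filter(records, DemuxConfig(umi_mode=True))
    assert len(kept) == 40
    assert frac == pytest.approx(2 / 3)


def test_clone_filter_edge_rules():
    cfg = DemuxConfig(umi_mode=True)
    distinct = [(f"r{i}", "A" * 40, "C" * 40, f"{'ACGT'[i % 4] * 8}")
                for i in range(4)]
    kept, frac = clone_filter(distinct, cfg)
    assert len(kept) == 4 and frac == 0.0
    # same 8N tag, different inserts: both retained
    shared = [("a", "AAAA" * 10, "C" * 40, "ACGTACGT"),
              ("b", "TTTT" * 10, "C" * 40, "ACGTACGT")]
    kept, frac = clone_filter(shared, cfg)
    assert len(kept) == 2 and frac == 0.0
    with pytest.raises(ValueError, match="I2"):
        clone_filter([("a", "A" * 40, "C" * 40, None)], cfg)


# ----------------------------------------------------------------- demux_run

@pytest.fixture(scope="module")
def simulated_run(table, registry, tmp_path_factory):
    from radtrio.adapters import make_plate_layout

    layout = make_plate_layout(table, 1, external=("ACGTACGT", "TGCATGCA"),
                               n_rows=2, n_cols=3)
    cfg = SimulationConfig(seed=17, recut_probability=0.0, depth=3,
                           error_rate=0.0, read_length=150)
    mols, truth = simulate_plate(table, registry, layout, cfg,
                                 n_loci_per_sample=20)
    quads = generate_reads(mols, cfg)
    out = tmp_path_factory.mktemp("sim")
    paths = write_fastq_streams(quads, out)
    truthmap = {}
    for line in paths["truth"].read_text().splitlines()[1:]:
        rid, sample, cls, mid, dg = line.split("\t")
        truthmap[rid] = (sample, cls)
    return layout, cfg, paths, truthmap, out


def test_error_free_round_trip_is_exact(simulated_run, design1_spec):
    layout, cfg, paths, truthmap, out = simulated_run
    stats = demux_run(paths["R1"], paths["R2"], paths["I1"], paths["I2"],
                      layout, None, design1_spec, DemuxConfig(),
                      out / "exact")
    assert stats.unassigned == {}
    expected_desired = Counter(s for s, c in truthmap.values()
                               if c == "desired")
    expected_third = Counter(s for s, c in truthmap.values()
                             if c == "third_site_locus")
    assert dict(stats.per_sample) == dict(expected_desired)
    assert dict(stats.third_per_sample) == dict(expected_third)
    assert stats.total_reads == len(truthmap)


def test_partition_property_and_trimmed_output(simulated_run, design1_spec):
    layout, cfg, paths, truthmap, out = simulated_run
    stats = demux_run(paths["R1"], paths["R2"], paths["I1"], paths["I2"],
                      layout, None, design1_spec, DemuxConfig(),
                      out / "part")
    binned = (sum(stats.per_sample.values())
              + sum(stats.third_per_sample.values())
              + sum(stats.unassigned.values()))
    assert binned == stats.total_reads
    # trimmed reads start at the first genomic base (after tag + remnant)
    some_well = next(iter(stats.per_sample))
    first = (out / "part" / f"{some_well}_R1.fastq").read_text().splitlines()
    assert not first[1].startswith(
        layout.wells[some_well][0].sequence)


def test_disabled_radcheck_retains_third_reads_in_sample(
        simulated_run, design1_spec):
    layout, cfg, paths, truthmap, out = simulated_run
    config = DemuxConfig(radcheck_mode="disabled",
                         third_enzyme_handling="retain")
    stats = demux_run(paths["R1"], paths["R2"], paths["I1"], paths["I2"],
                      layout, None, design1_spec, config, out / "disabled")
    per_truth = Counter(s for s, _ in truthmap.values())
    assert dict(stats.per_sample) == dict(per_truth)  # all reads in-sample
    props = third_enzyme_proportion(stats)
    expected_third = Counter(s for s, c in truthmap.values()
                             if c == "third_site_locus")
    assert dict(stats.third_per_sample) == dict(expected_third)
    assert props["pooled"] == pytest.approx(
        sum(expected_third.values()) / len(truthmap))


def test_rescue1_with_errors_never_misassigns(table, registry, design1_spec,
                                              tmp_path):
    """Substitutions at 1% may only push reads to unassigned, never to the
    wrong well; assignment stays >= 99%.

    Run without third-enzyme loci: an error inside a third remnant is
    (deliberately, conservatively) unrescuable, so the two-enzyme library
    isolates the assignment property."""
    from radtrio.adapters import make_plate_layout

    layout = make_plate_layout(table, 1, external=("ACGTACGT", "TGCATGCA"),
                               n_rows=4, n_cols=6)
    cfg = SimulationConfig(seed=23, recut_probability=0.0, depth=20,
                           error_rate=0.01, read_length=150)
    mols, _ = simulate_plate(table, registry, layout, cfg,
                             n_loci_per_sample=40, third_fraction=0.0)
    quads = generate_reads(mols, cfg)
    paths = write_fastq_streams(quads, tmp_path)
    truthmap = {}
    for line in paths["truth"].read_text().splitlines()[1:]:
        rid, sample, cls, mid, dg = line.split("\t")
        truthmap[rid] = sample
    config = DemuxConfig(radcheck_mode="rescue1")
    stats = demux_run(paths["R1"], paths["R2"], paths["I1"], paths["I2"],
                      layout, None, design1_spec, config, tmp_path / "out")
    # re-read bins to compare assigned well vs truth per read
    misassigned = 0
    assigned = 0
    for well in set(stats.per_sample) | set(stats.third_per_sample):
        for suffix in ("", "_third"):
            path = tmp_path / "out" / f"{well}{suffix}_R1.fastq"
            if not path.exists():
                continue
            for line in path.read_text().splitlines()[::4]:
                rid = line[1:].split()[0]
                assigned += 1
                if truthmap[rid] != well:
                    misassigned += 1
    assert misassigned == 0
    assert assigned / stats.total_reads >= 0.99


def test_desynchronized_streams_raise(simulated_run, design1_spec, tmp_path):
    layout, cfg, paths, truthmap, out = simulated_run
    truncated = tmp_path / "trunc.fastq"
    lines = paths["R2"].read_text().splitlines()
    truncated.write_text("\n".join(lines[:-4]) + "\n")
    with pytest.raises(ValueError, match="desynchronized"):
        demux_run(paths["R1"], truncated, paths["I1"], paths["I2"],
                  layout, None, design1_spec, DemuxConfig(), tmp_path / "o")


def test_empty_input_gives_zero_stats(table, design1_spec, tmp_path):
    from radtrio.adapters import make_plate_layout

    for name in ("r1", "r2", "i1", "i2"):
        (tmp_path / f"{name}.fastq").write_text("")
    layout = make_plate_layout(table, 1, n_rows=1, n_cols=1)
    stats = demux_run(tmp_path / "r1.fastq", tmp_path / "r2.fastq",
                      tmp_path / "i1.fastq", tmp_path / "i2.fastq",
                      layout, None, design1_spec, DemuxConfig(),
                      tmp_path / "out")
    assert stats.total_reads == 0 and stats.retained == 0
    assert stats.retained_fraction == 0.0


def test_third_enzyme_proportion_degenerate_cases():
    from radtrio.demux import DemuxStats

    all_third = DemuxStats(total_reads=10,
                           third_per_sample={"A01": 10},
                           intended_per_sample={})
    assert third_enzyme_proportion(all_third)["pooled"] == 1.0
    none_third = DemuxStats(total_reads=10,
                            intended_per_sample={"A01": 10})
    assert third_enzyme_proportion(none_third)["pooled"] == 0.0
    empty = DemuxStats()
    assert third_enzyme_proportion(empty)["pooled"] is None
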