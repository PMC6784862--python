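"""Non-reference extraction cascade, ORF families and CNV matrices."""

import numpy as np
import pandas as pd
import pytest
import networkx as nx

from yeastpop.align import KmerAligner, best_pair_block, records_to_blast6, blast6_to_records
from yeastpop.pangenome import (
    ORF,
    _merge_intervals,
    clade_cnv_contrast,
    collapse_orfs,
    extract_nonreference,
    orf_content_distance,
    orf_copy_number,
    presence_absence,
    similarity_edges,
)
from yeastpop.simulate import (
    SimulationConfig,
    simulate_assemblies,
    simulate_orf_content,
    simulate_population,
)

BASES = np.array(list("ACGT"))


def _seq(rng, n):
    return "".join(BASES[rng.integers(4, size=n)])


def _mutate(rng, seq, rate):
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    arr[hit] = BASES[(np.searchsorted(BASES, arr[hit]) + rng.integers(1, 4, hit.sum())) % 4]
    return "".join(arr)


@pytest.fixture(scope="module")
def reference(request):
    rng = np.random.default_rng(42)
    ref = _seq(rng, 30_000)
    return ref, KmerAligner({"ref": ref}), rng


class TestExtractionCascade:
    def test_short_fully_aligned_contig_dropped(self, reference):
        ref, aligner, rng = reference
        contig = ref[1000:1090]  # 90 bp, aligns at 100%
        recs = aligner.align(contig, "ctg")
        out = extract_nonreference({"ctg": contig}, recs, aligner.align)
        assert out == {}

    def test_midsize_block_excised_keeping_flanks(self, reference):
        ref, aligner, rng = reference
        novel_a, novel_b = _seq(rng, 350), _seq(rng, 350)
        contig = novel_a + ref[5000:5300] + novel_b
        recs = aligner.align(contig, "ctg")
        out = extract_nonreference({"ctg": contig}, recs, aligner.align)
        assert len(out) == 2
        assert novel_a in out.values() and novel_b in out.values()

    def test_long_block_segmented_and_removed(self, reference):
        ref, aligner, rng = reference
        novel = _seq(rng, 600)
        contig = ref[2000:4000] + novel
        recs = aligner.align(contig, "ctg")
        out = extract_nonreference({"ctg": contig}, recs, aligner.align)
        assert len(out) == 1
        piece = next(iter(out.values()))
        assert novel in piece
        # residual reference carried into the piece stays below the
        # 187-bp re-alignment floor
        assert len(piece) < len(novel) + 250

    def test_small_aligned_contig_with_short_flank_dropped(self, reference):
        ref, aligner, rng = reference
        contig = ref[8000:8180] + _seq(rng, 40)  # 180-bp block, contig < block+75
        recs = aligner.align(contig, "ctg")
        assert extract_nonreference({"ctg": contig}, recs, aligner.align) == {}

    def test_unaligned_contig_kept_whole(self, reference):
        _, aligner, rng = reference
        contig = _seq(rng, 800)
        out = extract_nonreference({"ctg": contig}, [], aligner.align)
        assert list(out.values()) == [contig]

    def test_unknown_contig_in_alignment_rejected(self, reference):
        ref, aligner, _ = reference
        recs = aligner.align(ref[:500], "ghost")
        with pytest.raises(ValueError):
            extract_nonreference({"ctg": "ACGT" * 100}, recs, aligner.align)

    def test_duplicate_sequence_deduplicated(self, reference):
        _, aligner, rng = reference
        novel = _seq(rng, 500)
        contigs = {"a": novel + _seq(rng, 50), "b": novel}
        out = extract_nonreference(contigs, [], aligner.align, deduplicate=True)
        assert len(out) == 1
        assert next(iter(out)).startswith("a")  # longer survivor

    def test_retained_pieces_never_realign(self, reference):
        """Cascade invariant: nothing retained re-aligns to the
        reference at > 95% identity over >= 187 bp."""
        ref, aligner, rng = reference
        contigs = {}
        for j in range(8):
            a = int(rng.integers(0, 20_000))
            contigs[f"c{j}"] = (
                ref[a : a + int(rng.integers(300, 2500))]
                + _seq(rng, int(rng.integers(200, 700)))
                + ref[a + 3000 : a + 3000 + int(rng.integers(300, 2500))]
            )
        recs = []
        for name, seq in contigs.items():
            recs.extend(aligner.align(seq, name))
        out = extract_nonreference(contigs, recs, aligner.align)
        for piece in out.values():
            hits = aligner.align(piece)
            assert not any(h.identity > 95 and h.length >= 187 for h in hits)


def test_merge_intervals_helper():
    assert _merge_intervals([(5, 10), (0, 6), (20, 30)]) == [(0, 10), (20, 30)]
    assert _merge_intervals([]) == []


class TestCollapse:
    def test_reference_copy_is_representative(self, rng):
        seq = _seq(rng, 900)
        orfs = {
            "ref1": ORF("ref1", seq, source="reference"),
            "nr1": ORF("nr1", seq, source="non-reference"),
        }
        cat = collapse_orfs(orfs)
        assert len(cat.families) == 1
        assert cat.representatives[next(iter(cat.families))] == "ref1"

    def test_transitive_edges_single_family(self):
        orfs = {k: ORF(k, "A" * 50) for k in "ABC"}
        cat = collapse_orfs(orfs, edges=[("A", "B"), ("B", "C")])
        assert sorted(next(iter(cat.families.values()))) == ["A", "B", "C"]

    def test_ninety_percent_identity_stays_separate(self, rng):
        a = _seq(rng, 900)
        b = _mutate(rng, a, 0.10)
        orfs = {"a": ORF("a", a), "b": ORF("b", b)}
        cat = collapse_orfs(orfs)
        assert len(cat.families) == 2

    def test_dubious_reference_deprioritized(self, rng):
        seq = _seq(rng, 600)
        orfs = {
            "dub": ORF("dub", seq, source="reference", dubious=True),
            "ok": ORF("ok", seq, source="reference"),
        }
        cat = collapse_orfs(orfs)
        assert list(cat.representatives.values()) == ["ok"]

    def test_idempotent_on_representatives(self, rng):
        seqs = {f"o{i}": _seq(rng, 600) for i in range(6)}
        orfs = {k: ORF(k, s) for k, s in seqs.items()}
        orfs["o0_copy"] = ORF("o0_copy", seqs["o0"])
        cat = collapse_orfs(orfs)
        reps = {r: orfs[r] for r in cat.representatives.values()}
        cat2 = collapse_orfs(reps)
        assert all(len(m) == 1 for m in cat2.families.values())

    def test_families_equal_brute_force_components(self, rng):
        base = [_seq(rng, int(rng.integers(300, 900))) for _ in range(30)]
        seqs = {}
        for i, s in enumerate(base):
            seqs[f"o{i}"] = s
            if rng.random() < 0.4:
                seqs[f"o{i}d"] = _mutate(rng, s, 0.02)  # 98% identical twin
        orfs = {k: ORF(k, s) for k, s in seqs.items()}
        cat = collapse_orfs(orfs)
        g = nx.Graph()
        g.add_nodes_from(seqs)
        g.add_edges_from(similarity_edges(seqs))
        expected = sorted(sorted(c) for c in nx.connected_components(g))
        assert sorted(sorted(m) for m in cat.families.values()) == expected


class TestCopyNumberAndPresence:
    def test_ratio_definition(self):
        orf_cov = pd.DataFrame({"o1": [60.0], "o2": [0.0], "o3": [15.0]}, index=["i"])
        chrom_cov = pd.DataFrame(np.full((1, 5), 30.0), index=["i"])
        cnv = orf_copy_number(orf_cov, chrom_cov)
        assert cnv.loc["i", "o1"] == pytest.approx(2.0)
        assert cnv.loc["i", "o2"] == 0.0
        assert cnv.loc["i", "o3"] == pytest.approx(0.5)

    def test_zero_coverage_isolate_excluded(self):
        orf_cov = pd.DataFrame({"o1": [60.0, 10.0]}, index=["a", "b"])
        chrom_cov = pd.DataFrame([[30.0] * 3, [0.0] * 3], index=["a", "b"])
        cnv = orf_copy_number(orf_cov, chrom_cov)
        assert cnv.attrs["excluded"] == ["b"]
        assert list(cnv.index) == ["a"]

    def test_rescaling_invariance(self, rng):
        orf_cov = pd.DataFrame(rng.uniform(0, 100, (4, 6)))
        chrom_cov = pd.DataFrame(rng.uniform(20, 40, (4, 8)))
        c1 = orf_copy_number(orf_cov, chrom_cov)
        c2 = orf_copy_number(orf_cov * 7.5, chrom_cov * 7.5)
        assert np.allclose(c1, c2)

    def test_core_variable_partition(self):
        cnv = pd.DataFrame(
            {"core": [1.0, 1.1, 0.9], "var": [1.0, 0.05, 1.2], "absent": [0.0, 0.0, 0.1]}
        )
        presence, core, variable = presence_absence(cnv, threshold=0.2)
        assert core == ["core"]
        assert set(variable) == {"var", "absent"}
        assert len(core) + len(variable) == cnv.shape[1]
        assert presence.loc[1, "var"] == 0  # copy 0.05 below threshold

    def test_planted_presence_recovered(self):
        cfg = SimulationConfig(seed=8, n_isolates=40)
        _, truth = simulate_population(cfg)
        orf_cov, chrom_cov = simulate_orf_content(truth, cfg)
        cnv = orf_copy_number(orf_cov, chrom_cov)
        presence, _, _ = presence_absence(cnv)
        truth_presence = (truth.orf_copy > 0).astype(int)
        mis = (presence.to_numpy() != truth_presence).mean()
        assert mis <= 0.02


class TestDistancesAndContrast:
    def test_orf_distance_examples(self):
        p = pd.DataFrame([[1, 1, 0], [1, 0, 1], [1, 1, 0]], index=list("abc"))
        d = orf_content_distance(p)
        assert d.loc["a", "b"] == 2
        assert d.loc["a", "c"] == 0
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_identical_groups_no_difference(self, rng):
        cnv = pd.DataFrame(
            np.tile(rng.uniform(0, 2, (4, 10)), (2, 1)),
            index=[f"i{j}" for j in range(8)],
        )
        clades = pd.Series(["c1", "c1", "c2", "c2", "c3", "c3", "c4", "c4"], index=cnv.index)
        res = clade_cnv_contrast(cnv, clades, {"c1": "A", "c2": "A", "c3": "B", "c4": "B"})
        assert res.p_value > 0.9

    def test_planted_group_inflation_detected(self, rng):
        base = rng.uniform(0.8, 1.2, (16, 40))
        base[8:] += 0.8  # one group's clades carry inflated copy numbers
        cnv = pd.DataFrame(base, index=[f"i{j}" for j in range(16)])
        clades = pd.Series(
            [f"c{j // 4}" for j in range(16)], index=cnv.index
        )
        groups = {"c0": "wild", "c1": "wild", "c2": "dom", "c3": "dom"}
        res = clade_cnv_contrast(cnv, clades, groups)
        assert res.p_value < 0.01

    def test_clade_median(self):
        cnv = pd.DataFrame({"o": [1.0, 1.0, 2.0, 5.0]}, index=list("abcd"))
        clades = pd.Series(["x", "x", "x", "y"], index=cnv.index)
        res = clade_cnv_contrast(cnv, clades, {"x": "A", "y": "B"})
        assert res.clade_medians.loc["x", "o"] == 1.0

    def test_group_without_clades_rejected(self, rng):
        cnv = pd.DataFrame(rng.uniform(0, 2, (4, 5)), index=list("abcd"))
        clades = pd.Series(["c1"] * 4, index=cnv.index)
        with pytest.raises(ValueError):
            clade_cnv_contrast(cnv, clades, {"c1": "A", "c9": "B"})


class TestEndToEndOnAssemblies:
    def test_planted_novel_orfs_recovered(self):
        cfg = SimulationConfig(seed=2, n_core_orfs=30, n_variable_orfs=30)
        asm = simulate_assemblies(cfg, n_isolates=8)
        aligner = KmerAligner(asm.reference)
        retained = {}
        for iso, ctgs in asm.contigs.items():
            recs = []
            for name, seq in ctgs.items():
                recs.extend(aligner.align(seq, name, seed_step=7))
            retained.update(
                extract_nonreference(ctgs, recs, aligner.align, deduplicate=False)
            )
        present = [o for o in asm.novel_orfs if asm.presence[o].any()]
        hits = sum(
            any(asm.novel_orfs[o] in piece for piece in retained.values())
            for o in present
        )
        assert hits / len(present) >= 0.9


def test_blast6_roundtrip(reference):
    ref, aligner, rng = reference
    recs = aligner.align(ref[1000:1600], "q")
    df = records_to_blast6(recs)
    assert list(df.columns[:4]) == ["qseqid", "sseqid", "pident", "length"]
    back = blast6_to_records(df)
    assert back[0].qstart == recs[0].qstart and back[0].send == recs[0].send
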