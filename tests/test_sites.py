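import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apakit import sites
from apakit.simulate import events_to_sam
from apakit.sites import (
    extract_cleavage_events,
    classify_site_region,
    classify_site_regions,
    map_to_annotation,
    merge_cleavage_sites,
)


def _events(positions, strand="+", contig="chr1", sample="s1"):
    return pd.DataFrame(
        {
            "contig": contig,
            "position": list(positions),
            "strand": strand,
            "sample_id": sample,
        }
    )


def _annotation(rows):
    return pd.DataFrame(
        [
            {
                "contig": c,
                "start": p,
                "end": p + 1,
                "name": name,
                "score": 0,
                "strand": s,
            }
            for c, p, s, name in rows
        ]
    )


class TestExtract:
    def test_bam_orientation_plus(self, tmp_path, sim):
        """Read aligned + at [100,250) -> event at 249; - at [100,250) -> 100."""
        ev = pd.DataFrame(
            {
                "contig": ["chr1", "chr1"],
                "position": [249, 100],
                "strand": ["+", "-"],
                "sample_id": ["s1", "s1"],
                "gene_id": ["g", "g"],
                "site_index": [1, 1],
            }
        )
        sam = events_to_sam(ev, {"chr1": 1000}, read_length=150)
        path = tmp_path / "reads.sam"
        path.write_text(sam)
        got = extract_cleavage_events(path, sample_id="s1")
        assert got["position"].tolist() == [249, 100]
        assert got["strand"].tolist() == ["+", "-"]

    def test_sam_roundtrip_matches_simulated_bed(self, tmp_path, sim):
        sam = events_to_sam(sim.events, {c: len(s) for c, s in sim.reference.genome.items()})
        path = tmp_path / "all.sam"
        path.write_text(sam)
        got = extract_cleavage_events(path, sample_id="pooled")
        want = sim.events[["contig", "position", "strand"]]
        key = lambda df: sorted(map(tuple, df.to_numpy()))
        assert key(got[["contig", "position", "strand"]]) == key(want)

    def test_reverse_orientation_flips(self, tmp_path):
        ev = _events([50])
        bed = pd.DataFrame(
            {"contig": "chr1", "start": [50], "end": [51], "name": "x",
             "score": 0, "strand": "+"}
        )
        path = tmp_path / "r.bed"
        bed.to_csv(path, sep="\t", header=False, index=False)
        got = extract_cleavage_events(path, "s1", orientation="reverse")
        assert got["strand"].tolist() == ["-"]

    def test_unknown_contig_errors(self, tmp_path):
        bed = pd.DataFrame(
            {"contig": "chrUn", "start": [5], "end": [6], "name": "x",
             "score": 0, "strand": "+"}
        )
        path = tmp_path / "u.bed"
        bed.to_csv(path, sep="\t", header=False, index=False)
        with pytest.raises(ValueError, match="unknown contig"):
            extract_cleavage_events(path, "s1", known_contigs={"chr1"})


class TestMerge:
    def test_three_point_instance(self):
        """{100, 110, 126}, gap 15: |110-126| = 16 > 15 -> two features."""
        res = merge_cleavage_sites(_events([100, 110, 126]), gap=15)
        spans = sorted(zip(res.features["start"], res.features["end"]))
        assert spans == [(100, 111), (126, 127)]

    def test_singleton(self):
        res = merge_cleavage_sites(_events([100]), gap=15)
        assert spans_and_counts(res) == [(100, 101, 1)]

    def test_negative_gap_errors(self):
        with pytest.raises(ValueError):
            merge_cleavage_sites(_events([1]), gap=-1)

    def test_strand_isolation(self):
        ev = pd.concat([_events([100]), _events([100], strand="-")])
        res = merge_cleavage_sites(ev, gap=15)
        assert len(res.features) == 2

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(0, 300), min_size=1, max_size=40),
        st.integers(0, 30),
    )
    def test_single_linkage_matches_bruteforce(self, positions, gap):
        res = merge_cleavage_sites(_events(positions), gap=gap)
        spans = sorted(zip(res.features["start"], res.features["end"]))
        # brute-force single linkage
        uniq = sorted(positions)
        clusters = [[uniq[0]]]
        for p in uniq[1:]:
            if p - clusters[-1][-1] <= gap:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        expect = [(c[0], c[-1] + 1) for c in clusters]
        assert spans == expect
        # conservation
        assert res.features["s1"].sum() == len(positions)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 500), min_size=1, max_size=30), st.randoms())
    def test_order_independence(self, positions, rnd):
        shuffled = list(positions)
        rnd.shuffle(shuffled)
        a = merge_cleavage_sites(_events(positions), 15).features
        b = merge_cleavage_sites(_events(shuffled), 15).features
        pd.testing.assert_frame_equal(a, b)

    def test_idempotent(self, sim):
        ev = sim.events[["contig", "position", "strand", "sample_id"]]
        once = merge_cleavage_sites(ev, 15)
        # re-merging the feature midpoints cannot split or join anything
        again = merge_cleavage_sites(once.assignments.drop(columns="feature_id"), 15)
        pd.testing.assert_frame_equal(once.features, again.features)

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.integers(0, 300), min_size=1, max_size=30))
    def test_gap_monotonicity(self, positions):
        n_prev = None
        for gap in (0, 5, 15, 50):
            n = len(merge_cleavage_sites(_events(positions), gap).features)
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestAnnotation:
    def test_containment_retained(self):
        res = merge_cleavage_sites(_events(range(100, 127)), gap=15)
        ann = _annotation([("chr1", 115, "+", "G|1")])
        pas = map_to_annotation(res, ann)
        assert pas["gene_id"].tolist() == ["G"]
        assert pas["s1"].sum() == 27

    def test_no_overlap_dropped(self):
        res = merge_cleavage_sites(_events([100, 110]), gap=15)
        ann = _annotation([("chr1", 300, "+", "G|1")])
        assert map_to_annotation(res, ann).empty

    def test_strand_mismatch_dropped(self):
        res = merge_cleavage_sites(_events([100]), gap=15)
        ann = _annotation([("chr1", 100, "-", "G|1")])
        assert map_to_annotation(res, ann).empty

    def test_wide_annotation_errors(self):
        res = merge_cleavage_sites(_events([100]), gap=15)
        ann = _annotation([("chr1", 100, "+", "G|1")])
        ann.loc[0, "end"] = 102
        with pytest.raises(ValueError, match="single-base"):
            map_to_annotation(res, ann)

    def test_multi_site_split_nearest(self):
        """Events split to the nearest of two annotated sites in one feature."""
        res = merge_cleavage_sites(_events([100, 101, 110, 111, 112]), gap=15)
        ann = _annotation([("chr1", 100, "+", "G|2"), ("chr1", 111, "+", "G|1")])
        pas = map_to_annotation(res, ann).set_index("site_pos")
        assert pas.loc[100, "s1"] == 2
        assert pas.loc[111, "s1"] == 3

    def test_distal_first_indexing_minus_strand(self):
        ev = _events([100, 200], strand="-")
        res = merge_cleavage_sites(ev, gap=15)
        ann = _annotation([("chr1", 100, "-", "G|x"), ("chr1", 200, "-", "G|y")])
        pas = map_to_annotation(res, ann).set_index("site_pos")
        # '-' strand: smaller coordinate is more distal
        assert pas.loc[100, "site_index"] == 1
        assert pas.loc[200, "site_index"] == 2

    def test_simulator_roundtrip_counts(self, sim, samples):
        merged = merge_cleavage_sites(
            sim.events[["contig", "position", "strand", "sample_id"]], 15
        )
        pas = map_to_annotation(merged, sim.reference.pas_annotation)
        got = (
            pas.sort_values(["gene_id", "site_index"])[["gene_id", "site_index"] + samples]
            .reset_index(drop=True)
        )
        want = sim.counts[sim.counts[samples].sum(axis=1) > 0]
        want = (
            want.sort_values(["gene_id", "site_index"])[["gene_id", "site_index"] + samples]
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(got, want)


class TestRegions:
    def test_simulated_sites_are_3utr(self, sim, samples):
        merged = merge_cleavage_sites(
            sim.events[["contig", "position", "strand", "sample_id"]], 15
        )
        pas = map_to_annotation(merged, sim.reference.pas_annotation)
        labeled, fractions = classify_site_regions(
            pas, sim.reference.gene_models, samples
        )
        assert (labeled["region"] == "3UTR").all()
        assert fractions["3UTR"] == 1.0

    def test_region_labels_by_position(self, sim):
        model = sim.reference.gene_models.iloc[0]
        assert model["strand"] == "+"
        g0 = model["start"]
        assert classify_site_region(g0 + 10, model) == "5UTR"  # before thickStart
        assert classify_site_region(g0 + 100, model) == "CDS"
        assert classify_site_region(g0 + 250, model) == "intron"  # between blocks
        assert classify_site_region(model["thick_end"] + 5, model) == "3UTR"
        assert classify_site_region(model["end"] + 5, model) == "intergenic"

    def test_unknown_gene_warns(self, sim, samples):
        pas = pd.DataFrame(
            {
                "gene_id": ["nope"],
                "site_index": [1],
                "contig": ["chr1"],
                "strand": ["+"],
                "site_pos": [100],
                **{s: [1] for s in samples},
            }
        )
        with pytest.warns(UserWarning, match="absent"):
            labeled, fractions = classify_site_regions(
                pas, sim.reference.gene_models, samples
            )
        assert labeled["region"].tolist() == ["unknown"]


def spans_and_counts(res):
    return sorted(
        zip(res.features["start"], res.features["end"], res.features["s1"])
    )
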