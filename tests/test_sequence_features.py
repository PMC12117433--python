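"""Sequence features: hand-derived examples plus brute-force scan oracles."""

import numpy as np
import pandas as pd
import pytest

from scig.io_formats import GeneModel, IntervalTable, Motif, MotifSet, revcomp
from scig.sequence_features import (
    SequenceFeatureConfig,
    architecture_features,
    build_sequence_feature_table,
    codon_bias_features,
    conservation_aggregates,
    count_motif_hits,
    motif_scan_counts,
    nucleotide_composition,
    site_overlap_counts,
    tss_distance,
)


# --- independent oracles ---------------------------------------------------


def naive_pwm_hits(seq: str, pwm: np.ndarray, score_fraction: float) -> int:
    """All-window O(n*m) scan on both strands, scored literally."""
    logodds = np.log((pwm + 1e-6) / 0.25)
    threshold = score_fraction * logodds.max(axis=0).sum()
    total = 0
    for strand_seq in (seq, revcomp(seq)):
        L = pwm.shape[1]
        for i in range(len(strand_seq) - L + 1):
            window = strand_seq[i : i + L]
            if "N" in window:
                continue
            score = sum(logodds["ACGT".index(b), j] for j, b in enumerate(window))
            if score >= threshold:
                total += 1
    return total


def naive_consensus_hits(seq: str, consensus: str) -> int:
    total = 0
    for strand_seq in (seq, revcomp(seq)):
        for i in range(len(strand_seq) - len(consensus) + 1):
            if strand_seq[i : i + len(consensus)] == consensus:
                total += 1
    return total


def naive_overlap_count(region_ivs, sites) -> int:
    count = 0
    for s, e in sites:
        if any(s < b and e > a for a, b in region_ivs):
            count += 1
    return count


# --- architecture ----------------------------------------------------------


class TestArchitecture:
    def test_two_exon_gene(self):
        g = GeneModel("g", "c1", "+", 0, 1000, exons=[(0, 200), (800, 1000)])
        feats = architecture_features(g)
        assert feats["gene_length"] == 1000
        assert feats["exon_length"] == 400
        assert feats["intron_length"] == 600
        assert feats["n_exons"] == 2
        assert feats["n_introns"] == 1
        assert feats["intron_exon_ratio"] == 0.5

    def test_single_exon_and_missing_utr(self):
        g = GeneModel("g", "c1", "+", 0, 300, exons=[(0, 300)])
        feats = architecture_features(g)
        assert feats["intron_length"] == 0
        assert feats["intron_exon_ratio"] == 0
        assert feats["utr3_length"] == 0


# --- composition -----------------------------------------------------------


class TestComposition:
    def test_hand_counts(self):
        feats = nucleotide_composition("AATT")
        assert feats["nt_A"] == 0.5
        assert feats["nt_T"] == 0.5
        assert feats["at_content"] == 1.0
        # overlapping dinucleotides of AATT: AA, AT, TT
        assert feats["nt_AT"] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(3))
    def test_mono_frequencies_normalized(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=200))
        feats = nucleotide_composition(seq)
        mono = sum(feats[f"nt_{b}"] for b in "ACGT")
        assert mono == pytest.approx(1.0)
        tri = sum(v for k, v in feats.items() if len(k) == 6 and k.startswith("nt_"))
        assert tri == pytest.approx(1.0)

    def test_empty_sequence_all_missing(self):
        feats = nucleotide_composition("")
        assert all(np.isnan(v) for v in feats.values())


class TestCodonBias:
    def test_glycine_group(self):
        # GGT GGC ATG: two of three codons are glycine
        feats = codon_bias_features("GGTGGCATG")
        assert feats["codon_G_total_proportion"] == pytest.approx(2 / 3)
        # glycine codon frequencies {1/3, 1/3, 0, 0}: mean 1/6, pop sd 1/6
        assert feats["codon_G_mean"] == pytest.approx(1 / 6)
        assert feats["codon_G_cv"] == pytest.approx(1.0)
        # single-codon group (Met present): zero dispersion
        assert feats["codon_M_cv"] == 0.0

    def test_non_triplet_length_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            codon_bias_features("GGTG")


# --- motif scanning --------------------------------------------------------


def _one_gene_genome(tmp_path, seq):
    from scig.io_formats import read_genome

    fa = tmp_path / "g.fa"
    fa.write_text(f">c1\n{seq}\n")
    return read_genome(fa)


class TestMotifScan:
    def test_consensus_density(self, tmp_path):
        genome = _one_gene_genome(tmp_path, "AACAAC")
        g = GeneModel("g", "c1", "+", 0, 6, exons=[(0, 6)])
        motifs = MotifSet([Motif("m", consensus="AAC")])
        feats = motif_scan_counts(g, genome, motifs, ["gene_body"], 0.8)
        # two forward AAC occurrences, none on the reverse strand (GTT absent)
        assert feats["tf_motif_density_gene_body"] == pytest.approx(2 / 6 * 1000)

    def test_absent_motif_zero(self, tmp_path):
        genome = _one_gene_genome(tmp_path, "CCCCCC")
        g = GeneModel("g", "c1", "+", 0, 6, exons=[(0, 6)])
        motifs = MotifSet([Motif("m", consensus="AAA")])
        feats = motif_scan_counts(g, genome, motifs, ["gene_body"], 0.8)
        assert feats["tf_motif_density_gene_body"] == 0.0

    def test_deterministic_pwm_exact_matches(self):
        # one deterministic column per base spells ACGT; at fraction 1.0 only
        # exact matches hit: 2 forward plus 2 reverse (ACGT is palindromic)
        pwm = np.eye(4)[:, [0, 1, 2, 3]]
        pwm = np.zeros((4, 4))
        for j, b in enumerate("ACGT"):
            pwm["ACGT".index(b), j] = 1.0
        motif = Motif("m", pwm=pwm)
        assert count_motif_hits("ACGTACGT", motif, 1.0) == 4
        assert naive_pwm_hits("ACGTACGT", pwm, 1.0) == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_scan_on_random_input(self, seed):
        """Vectorized scan equals the literal all-window oracle exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 500))
        seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        L = int(rng.integers(4, 9))
        pwm = rng.dirichlet(np.ones(4) * 0.5, size=L).T
        motif = Motif("m", pwm=pwm)
        frac = float(rng.uniform(0.5, 0.95))
        assert count_motif_hits(seq, motif, frac) == naive_pwm_hits(seq, pwm, frac)

    def test_window_never_spans_intervals(self, tmp_path):
        # AAC straddling the two exons must not be counted
        genome = _one_gene_genome(tmp_path, "AAACAA")
        g = GeneModel("g", "c1", "+", 0, 6, exons=[(0, 2), (3, 6)])
        motifs = MotifSet([Motif("m", consensus="AAC")])
        feats = motif_scan_counts(g, genome, motifs, ["exons"], 0.8)
        assert feats["tf_motif_density_exons"] == 0.0


# --- site overlap ----------------------------------------------------------


class TestSiteOverlap:
    def _table(self, rows):
        return IntervalTable(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def test_exon_overlap_counting(self):
        g = GeneModel("g", "c1", "+", 100, 400, exons=[(100, 200), (300, 400)])
        sites = self._table(
            [("c1", 150, 160), ("c1", 250, 260), ("c1", 390, 410)]
        )
        feats = site_overlap_counts(g, sites, ["exons"], prefix="rbp_site")
        assert feats["rbp_site_density_exons"] == pytest.approx(2 / 200 * 1000)

    def test_wrong_chrom_and_abutting_site(self):
        g = GeneModel("g", "c1", "+", 100, 200, exons=[(100, 200)])
        other = self._table([("c2", 120, 130)])
        assert site_overlap_counts(g, other, ["exons"], "s")["s_density_exons"] == 0.0
        # half-open: [200, 210) does not touch [100, 200)
        abutting = self._table([("c1", 200, 210)])
        assert site_overlap_counts(g, abutting, ["exons"], "s")["s_density_exons"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        exon_starts = np.sort(rng.choice(np.arange(0, 5000, 10), size=4, replace=False))
        exons = [(int(s), int(s + rng.integers(5, 200))) for s in exon_starts]
        exons = [(s, e) for s, e in exons]
        g = GeneModel("g", "c1", "+", 0, 6000,
                      exons=[(s, min(e, 6000)) for s, e in exons])
        raw = [(int(s), int(s + rng.integers(1, 60)))
               for s in rng.integers(0, 6000, size=40)]
        sites = self._table([("c1", s, e) for s, e in raw])
        feats = site_overlap_counts(g, sites, ["exons"], "s")
        exon_len = sum(e - s for s, e in g.exons)
        expected = naive_overlap_count(g.exons, raw) / exon_len * 1000
        assert feats["s_density_exons"] == pytest.approx(expected)


# --- conservation ----------------------------------------------------------


class TestConservation:
    def _track(self, rows):
        from scig.io_formats import ConservationTrack

        return ConservationTrack(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        )

    def test_mean_median_over_covered_bases(self):
        g = GeneModel("g", "c1", "+", 0, 4, exons=[(0, 4)])
        track = self._track(
            [("c1", 0, 1, 1.0), ("c1", 1, 2, 2.0), ("c1", 2, 3, 3.0), ("c1", 3, 4, 10.0)]
        )
        feats = conservation_aggregates(g, track, ["gene_body"])
        assert feats["cons_mean_gene_body"] == pytest.approx(4.0)
        assert feats["cons_median_gene_body"] == pytest.approx(2.5)

    def test_uncovered_region_missing(self):
        g = GeneModel("g", "c1", "+", 100, 200, exons=[(100, 200)])
        track = self._track([("c1", 0, 10, 1.0)])
        feats = conservation_aggregates(g, track, ["gene_body"])
        assert np.isnan(feats["cons_mean_gene_body"])

    def test_constant_track(self):
        g = GeneModel("g", "c1", "+", 0, 50, exons=[(0, 50)])
        track = self._track([("c1", 0, 50, 0.7)])
        feats = conservation_aggregates(g, track, ["gene_body"])
        assert feats["cons_mean_gene_body"] == pytest.approx(0.7)
        assert feats["cons_median_gene_body"] == pytest.approx(0.7)


# --- TSS distance ----------------------------------------------------------


class TestTssDistance:
    def _genes(self, tss_list):
        return [
            GeneModel(f"g{i}", "c1", "+", t, t + 100, exons=[(t, t + 100)])
            for i, t in enumerate(tss_list)
        ]

    def test_nearest_neighbour(self):
        genes = self._genes([1000, 5000, 5200])
        assert tss_distance(genes[1], genes) == 200

    def test_symmetry_and_singleton(self):
        pair = self._genes([0, 10])
        assert tss_distance(pair[0], pair) == 10
        assert tss_distance(pair[1], pair) == 10
        solo = self._genes([500])
        assert np.isnan(tss_distance(solo[0], solo))


# --- table assembly --------------------------------------------------------


class TestFeatureTable:
    def test_shape_and_determinism(self, small_inputs):
        models = small_inputs["models"][:10]
        t1 = build_sequence_feature_table(
            models, small_inputs["genome"], small_inputs["motifs"],
            small_inputs["rbp"], small_inputs["mirna"], small_inputs["track"],
        )
        assert t1.df.shape[0] == 10
        t2 = build_sequence_feature_table(
            models, small_inputs["genome"], small_inputs["motifs"],
            small_inputs["rbp"], small_inputs["mirna"], small_inputs["track"],
        )
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_input_order_invariance(self, small_inputs):
        models = small_inputs["models"][:10]
        t1 = build_sequence_feature_table(
            models, small_inputs["genome"], small_inputs["motifs"],
            small_inputs["rbp"], small_inputs["mirna"], small_inputs["track"],
        )
        shuffled = list(models)[::-1]
        motifs_rev = MotifSet(list(small_inputs["motifs"].motifs)[::-1])
        t2 = build_sequence_feature_table(
            shuffled, small_inputs["genome"], motifs_rev,
            small_inputs["rbp"], small_inputs["mirna"], small_inputs["track"],
        )
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_empty_motif_set_omits_motif_columns(self, small_inputs):
        t = build_sequence_feature_table(
            small_inputs["models"][:5], small_inputs["genome"], MotifSet([]),
        )
        assert not any(c.startswith("tf_motif_") for c in t.df.columns)

    def test_densities_finite_nonnegative(self, small_inputs):
        t = build_sequence_feature_table(
            small_inputs["models"][:20], small_inputs["genome"],
            small_inputs["motifs"], small_inputs["rbp"], small_inputs["mirna"],
            small_inputs["track"],
        )
        dens = t.df[[c for c in t.df.columns if "density" in c]]
        vals = dens.to_numpy()
        finite = vals[~np.isnan(vals)]
        assert (finite >= 0).all()
        freqs = t.df[[c for c in t.df.columns if c.startswith("nt_")]].to_numpy()
        f = freqs[~np.isnan(freqs)]
        assert ((f >= 0) & (f <= 1)).all()
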