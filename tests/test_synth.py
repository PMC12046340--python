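import json

import numpy as np
import pytest
from scipy import stats

from barcodepop import distmat
from barcodepop.codonsel import detect_frame, site_diversity
from barcodepop.hapnet import group_separation
from barcodepop.popgen import pairwise_fst
from barcodepop.synth import (
    SENSE_CODONS,
    SimulationConfig,
    _drop_mutations,
    _kingman_tree,
    _random_ancestor,
    make_deep_split_species,
    simulate,
)

_STOPS = {"TAA", "TAG", "AGA", "AGG"}


def has_internal_stop(seq):
    return any(
        seq[i:i + 3] in _STOPS for i in range(0, len(seq) - 2, 3)
    )


class TestDeterminismAndInvariants:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_species=8, seed=11, include_outgroup=True)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        simulate(cfg).write(d1)
        simulate(cfg).write(d2)
        for name in ("alignment.fasta", "metadata.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_zero_mutation_rate_collapses_everything(self):
        res = simulate(SimulationConfig(n_species=5, mu=0.0, seed=3))
        seqs = set(res.aligned.sequences())
        assert len(seqs) == 1  # all identical, within and between species

    def test_no_internal_stops_anywhere(self):
        res = simulate(SimulationConfig(n_species=20, seed=5,
                                        include_outgroup=True))
        for r in res.aligned:
            assert not has_internal_stop(r.sequence), r.seq_id

    def test_frame_recovered_for_every_species(self):
        res = simulate(SimulationConfig(n_species=100, seed=7))
        recovered = 0
        for sp, recs in res.aligned.by_species().items():
            frame = detect_frame([r.sequence for r in recs])
            assert frame.offset == 0
            recovered += 1
        assert recovered == 100

    def test_truth_records_configured_structure(self):
        cfg = SimulationConfig(n_species=6, seed=2)
        res = simulate(cfg)
        assert res.truth["frame"] == 0
        assert len(res.truth["species"]) == 6
        for info in res.truth["species"].values():
            assert info["theta"] == pytest.approx(
                2 * res.truth["mu"] * info["Ne"]
            )
            assert 0 < info["r"] <= 1

    def test_selection_map_non_increasing_in_ne(self):
        res = simulate(SimulationConfig(n_species=50, seed=9))
        info = sorted(
            res.truth["species"].values(), key=lambda v: v["Ne"]
        )
        rs = [v["r"] for v in info]
        assert all(a >= b for a, b in zip(rs, rs[1:]))


class TestDeepSplit:
    def ancestor(self, rng):
        return "".join(_random_ancestor(220, rng))

    def test_separation_equals_k_exactly(self, rng):
        pairs = make_deep_split_species(
            self.ancestor(rng), k=13, n_east=6, n_west=7, theta=0.002, rng=rng
        )
        from conftest import make_set

        a = make_set(
            [(f"s{i}", "X", seq, pop) for i, (pop, seq) in enumerate(pairs)]
        )
        assert group_separation(a, ["east"], ["west"]) == 13

    def test_zero_k_rejected(self, rng):
        with pytest.raises(ValueError):
            make_deep_split_species(
                self.ancestor(rng), k=0, n_east=2, n_west=2, theta=0.001,
                rng=rng,
            )

    def test_k_beyond_available_sites_rejected(self, rng):
        with pytest.raises(ValueError, match="4-fold"):
            make_deep_split_species(
                "GCT" * 4, k=13, n_east=2, n_west=2, theta=0.001, rng=rng
            )

    def test_group_sizes_as_requested(self, rng):
        pairs = make_deep_split_species(
            self.ancestor(rng), k=5, n_east=4, n_west=3, theta=0.001, rng=rng
        )
        labels = [p for p, _ in pairs]
        assert labels.count("east") == 4 and labels.count("west") == 3

    def test_no_stops_introduced(self, rng):
        pairs = make_deep_split_species(
            self.ancestor(rng), k=20, n_east=5, n_west=5, theta=0.01, rng=rng
        )
        for _, seq in pairs:
            assert not has_internal_stop(seq)


class TestStatisticalTargets:
    def test_realized_distances_match_configured_expectations(self):
        """Monte-Carlo over 200 replicates of the default survey: mean
        intraspecific K2P within 3 SE of the configured expectation, and
        mean interspecific K2P within 3 SE of the tree-exact expectation
        recorded in the truth output."""
        intra, inter, expected_tree = [], [], []
        for seed in range(200):
            res = simulate(SimulationConfig(seed=seed))
            m = distmat.pairwise_matrix(res.aligned)
            s = distmat.summarize(m, res.aligned.species_labels)
            intra.append(s.intra_mean)
            inter.append(s.inter_mean)
            expected_tree.append(res.truth["expected_inter_k2p_tree"])
        intra = np.array(intra)
        cfg = SimulationConfig()
        se = intra.std(ddof=1) / np.sqrt(len(intra))
        assert abs(intra.mean() - cfg.expected_intra_pi()) < 3 * se
        assert cfg.expected_intra_pi() == pytest.approx(0.004, abs=1e-9)
        diff = np.array(inter) - np.array(expected_tree)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se
        # the tree-exact expectation sits near the configured 18% target
        assert np.mean(expected_tree) == pytest.approx(
            cfg.inter_divergence, rel=0.08
        )

    def test_pi0_pi4_ratio_tracks_selection_factor(self, rng):
        """E[pi0/pi4] ~ r: with a fixed selection factor r on 0-fold sites,
        the ratio of mean diversities over 200 replicates recovers r."""
        r = 0.4
        theta = 0.02
        anc = _random_ancestor(220, rng)
        from barcodepop.codonsel import CLASS_0FOLD, classify_sites

        classes = classify_sites("".join(anc), 0)
        sel = np.array([c == CLASS_0FOLD for c in classes])
        pi0s, pi4s = [], []
        for _ in range(200):
            tree = _kingman_tree(8, rng)
            tips = _drop_mutations(tree, anc, theta / 2, rng, 8.0, sel, r)
            rec = site_diversity("sp", list(tips.values()), frame=0)
            pi0s.append(rec.pi0)
            pi4s.append(rec.pi4)
        pi0s, pi4s = np.array(pi0s), np.array(pi4s)
        ratio = pi0s.mean() / pi4s.mean()
        # delta-method SE of the ratio of means
        n = len(pi0s)
        se = ratio * np.sqrt(
            pi0s.var(ddof=1) / (n * pi0s.mean() ** 2)
            + pi4s.var(ddof=1) / (n * pi4s.mean() ** 2)
            - 2 * np.cov(pi0s, pi4s)[0, 1] / (n * pi0s.mean() * pi4s.mean())
        )
        assert abs(ratio - r) < 3 * se

    def test_pi4_increases_with_ne(self):
        """Rank correlation between realized 4-fold diversity and Ne > 0."""
        ne_vals, pi4_vals = [], []
        for seed in range(3):
            res = simulate(
                SimulationConfig(n_species=100, sample_size_range=(6, 6),
                                 seed=seed)
            )
            for sp, recs in res.aligned.by_species().items():
                rec = site_diversity(sp, [r.sequence for r in recs], frame=0)
                if rec.n4 > 0:
                    ne_vals.append(res.truth["species"][sp]["Ne"])
                    pi4_vals.append(rec.pi4)
        tau = stats.kendalltau(ne_vals, pi4_vals)
        assert tau.statistic > 0.3
        assert tau.pvalue < 1e-6
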