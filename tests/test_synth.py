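import math

import numpy as np
import pytest
from scipy.stats import norm

from pepdev.affinity import affinity_class
from pepdev.core import Modality, validate_record
from pepdev.synth import (
    CLASS_BALANCE_PRESETS,
    MOTIF,
    MOTIF_POSITION,
    SynthConfig,
    affinity_ground_truth,
    convert_to_smiles,
    gen_affinity_pairs,
    gen_binary_corpus,
    gen_halflife,
    gen_permeability_corpus,
)
from pepdev.core import AA_ALPHABET


class TestConfig:
    def test_balance_bounds(self):
        with pytest.raises(ValueError):
            SynthConfig(n=10, class_balance=1.0)

    def test_negative_noise(self):
        with pytest.raises(ValueError):
            SynthConfig(n=10, noise_sd=-0.1)


class TestBinaryCorpus:
    def test_reproducible(self):
        cfg = SynthConfig(n=50, seed=4)
        a = gen_binary_corpus(cfg)
        b = gen_binary_corpus(cfg)
        assert [(r.id, r.payload, r.labels) for r in a.records] == [
            (r.id, r.payload, r.labels) for r in b.records
        ]

    def test_all_records_valid(self):
        ds = gen_binary_corpus(SynthConfig(n=100, seed=1))
        for rec in ds.records:
            validate_record(rec)

    @pytest.mark.parametrize("balance", [0.22, 0.5, 0.78])
    def test_achieved_balance_within_3pct(self, balance):
        ds = gen_binary_corpus(SynthConfig(n=1500, class_balance=balance, seed=2))
        frac = np.mean(ds.labels())
        assert abs(frac - balance) <= 0.03

    def test_motif_rule_plants_motif_at_fixed_position(self):
        ds = gen_binary_corpus(
            SynthConfig(n=200, effect_size=8.0, noise_sd=0.01, seed=3), rule="motif"
        )
        pos = [r for r in ds.records if r.labels["hemolysis"] == 1.0]
        frac_at_pos = np.mean(
            [r.payload[MOTIF_POSITION : MOTIF_POSITION + len(MOTIF)] == MOTIF for r in pos]
        )
        assert frac_at_pos > 0.95
        # negatives carry the motif elsewhere (composition decoys)
        neg = [r for r in ds.records if r.labels["hemolysis"] == 0.0]
        assert np.mean([MOTIF in r.payload for r in neg]) > 0.95

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            gen_binary_corpus(SynthConfig(n=10, seed=0), rule="magic")

    def test_presets_reflect_imbalance(self):
        assert CLASS_BALANCE_PRESETS["hemolysis"] == pytest.approx(0.78)
        assert CLASS_BALANCE_PRESETS["non_fouling"] == pytest.approx(0.21)


class TestPermeabilityCorpus:
    def test_threshold_rule_applied(self):
        ds = gen_permeability_corpus(SynthConfig(n=400, seed=5))
        for rec in ds.records:
            v = rec.labels["permeability_pampa"]
            assert rec.labels["permeability_pampa_high"] == float(v >= -6.0)

    def test_boundary_value_labeled_high(self):
        # the smallest high-labeled value can never be below the boundary
        ds = gen_permeability_corpus(SynthConfig(n=2000, seed=6))
        high = [r.labels["permeability_pampa"] for r in ds.records
                if r.labels["permeability_pampa_high"] == 1.0]
        assert min(high) >= -6.0

    def test_mixture_tail_closed_form(self):
        """High fraction matches the Gaussian-mixture tail probability."""
        cfg = SynthConfig(n=10000, class_balance=0.5, seed=7)
        ds = gen_permeability_corpus(cfg, mixture_means=(-8.0, -5.0), mixture_sd=0.8)
        got = np.mean([r.labels["permeability_pampa_high"] for r in ds.records])
        want = 0.5 * norm.sf(-6.0, loc=-8.0, scale=0.8) + 0.5 * norm.sf(
            -6.0, loc=-5.0, scale=0.8
        )
        assert got == pytest.approx(want, abs=0.02)


class TestAffinityPairs:
    def test_noise_free_scores_match_formula_oracle(self):
        """An independent re-evaluation of the documented generator formula
        reproduces every score exactly (up to the corpus-level rescaling)."""
        cfg = SynthConfig(n=60, noise_sd=0.0, seed=8)
        pairs = gen_affinity_pairs(cfg)
        u, v, w, a = affinity_ground_truth(8, max_pep_len=10, max_prot_len=40)
        idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
        raws = []
        for p in pairs:
            pep, prot = p.peptide.payload, p.protein_seq
            P = sum(w[i] * u[idx[x]] for i, x in enumerate(pep)) / math.sqrt(len(pep))
            T = sum(a[j] * v[idx[y]] for j, y in enumerate(prot)) / math.sqrt(len(prot))
            raws.append(P + T + 0.5 * P * T)
        raws = np.array(raws)
        lo, hi = raws.min(), raws.max()
        want = 4.0 + (raws - lo) / (hi - lo) * 8.0
        got = np.array([p.score for p in pairs])
        assert np.allclose(got, want, atol=1e-12)

    def test_classes_derived_from_scores(self):
        pairs = gen_affinity_pairs(SynthConfig(n=100, noise_sd=0.2, seed=9))
        assert all(p.klass == affinity_class(p.score) for p in pairs)

    def test_reproducible(self):
        cfg = SynthConfig(n=30, seed=10)
        a = gen_affinity_pairs(cfg)
        b = gen_affinity_pairs(cfg)
        assert [(p.peptide.payload, p.protein_seq, p.score) for p in a] == [
            (p.peptide.payload, p.protein_seq, p.score) for p in b
        ]

    def test_score_range(self):
        pairs = gen_affinity_pairs(SynthConfig(n=200, noise_sd=0.0, seed=11))
        scores = [p.score for p in pairs]
        assert min(scores) == pytest.approx(4.0) and max(scores) == pytest.approx(12.0)


class TestHalfLife:
    def test_sparsity_cap(self):
        with pytest.raises(ValueError, match="capped"):
            gen_halflife(SynthConfig(n=600, seed=0))

    def test_hours_positive(self):
        hl, _ = gen_halflife(SynthConfig(n=100, seed=12))
        assert all(r.hours > 0 for r in hl)

    def test_latent_correlation(self):
        hl, stab = gen_halflife(SynthConfig(n=300, noise_sd=0.4, seed=13))
        log_hours = [np.log1p(r.hours) for r in hl]
        s = [stab.records[i].labels["stability"] for i in range(300)]
        assert np.corrcoef(log_hours, s)[0, 1] >= 0.6

    def test_shared_ids(self):
        hl, stab = gen_halflife(SynthConfig(n=50, seed=14), n_stability=200)
        stab_ids = {r.id for r in stab.records}
        assert all(r.peptide.id in stab_ids for r in hl)
        assert len(stab.records) == 200

    def test_reproducible(self):
        cfg = SynthConfig(n=40, seed=15)
        a, _ = gen_halflife(cfg)
        b, _ = gen_halflife(cfg)
        assert [(r.peptide.payload, r.hours) for r in a] == [
            (r.peptide.payload, r.hours) for r in b
        ]


class TestConvertToSmiles:
    def test_ids_and_labels_preserved(self):
        ds = gen_binary_corpus(SynthConfig(n=20, length_range=(4, 8), seed=16))
        smi = convert_to_smiles(ds)
        assert [r.id for r in smi.records] == [r.id for r in ds.records]
        assert all(r.modality is Modality.SMILES for r in smi.records)
        assert [r.labels for r in smi.records] == [r.labels for r in ds.records]

    def test_effect_monotonicity_gbt(self):
        """More planted signal never hurts the gbt head (median over seeds)."""
        from pepdev.embed import baseline_sequence_featurizer, mean_pool
        from pepdev.heads import HeadSpec, predict_head, train_head
        from pepdev.metrics import classification_metrics

        def median_f1(effect):
            f1s = []
            for seed in range(3):
                ds = gen_binary_corpus(
                    SynthConfig(n=400, effect_size=effect, noise_sd=0.2, seed=20 + seed)
                )
                X = [mean_pool(baseline_sequence_featurizer(r.payload)) for r in ds.records]
                y = np.array(ds.labels())
                head = train_head(HeadSpec("gbt", "binary", seed=seed), X[:320], y[:320])
                f1s.append(classification_metrics(y[320:], predict_head(head, X[320:])).f1)
            return np.median(f1s)

        assert median_f1(6.0) >= median_f1(1.0) - 0.02
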