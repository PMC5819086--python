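"""Synthetic proteome, evolution and search simulation."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from paleosap.digest import collapse_il
from paleosap.io import write_proteome_fasta
from paleosap.sim import (
    IdentificationModel,
    OrthologTruth,
    ReferenceProteome,
    SimulationConfig,
    SimulationConfigError,
    apply_substitutions,
    evolve_proteome,
    generate_reference_proteome,
    simulate_search,
)


def fasta_bytes(proteome):
    buf = io.StringIO()
    write_proteome_fasta(proteome, buf)
    return buf.getvalue().encode()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(n_proteins=0), "n_proteins"),
            (dict(drop_fraction=1.5), "drop_fraction"),
            (dict(divergence_per_db=(-1.0, 1.0)), "divergence_per_db"),
            (dict(outcome3_rate=0.7, outcome2_rate=0.5), "outcome3_rate"),
            (dict(digestion_mode="chymotryptic"), "digestion_mode"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(SimulationConfigError, match=field):
            SimulationConfig(**kwargs).validate()


class TestGenerateProteome:
    def test_determinism_byte_identical_fasta(self):
        config = SimulationConfig(n_proteins=5, seed=1)
        a = fasta_bytes(generate_reference_proteome(config))
        b = fasta_bytes(generate_reference_proteome(config))
        assert a == b

    def test_unique_accessions_and_standard_alphabet(self):
        config = SimulationConfig(n_proteins=20, n_contaminants=3, seed=2)
        prot = generate_reference_proteome(config)
        assert len(prot.accessions) == len(set(prot.accessions)) == 23
        assert len(prot.contaminants) == 3
        alphabet = set("ACDEFGHIKLMNPQRSTVWY")
        for seq in prot.proteins.values():
            assert set(seq) <= alphabet

    def test_mean_length_within_three_sd_of_uniform_law(self):
        # uniform on {100..500}: mean 300, variance (401^2 - 1)/12
        config = SimulationConfig(
            n_proteins=100, protein_length_range=(100, 500), seed=3
        )
        prot = generate_reference_proteome(config)
        lengths = np.array([len(s) for s in prot.proteins.values()])
        sd_mean = math.sqrt((401**2 - 1) / 12 / 100)
        assert abs(lengths.mean() - 300) < 3 * sd_mean


class TestEvolveProteome:
    def test_zero_divergence_is_identity(self):
        config = SimulationConfig(
            n_proteins=10,
            divergence_per_db=(0.0,),
            db_labels=("sister",),
            drop_fraction=0.0,
            mispredict_fraction=0.0,
            seed=4,
        )
        target = generate_reference_proteome(config)
        db, truth = evolve_proteome(target, 0, config)
        assert db.proteins == target.proteins
        assert truth.n_substitutions() == 0

    def test_truth_matches_sequence_diff_exactly(self):
        config = SimulationConfig(
            n_proteins=15,
            divergence_per_db=(2.0, 5.0),
            drop_fraction=0.1,
            mispredict_fraction=0.1,
            seed=5,
        )
        target = generate_reference_proteome(config)
        db, truth = evolve_proteome(target, 1, config)
        for acc, seq in target.proteins.items():
            if acc in truth.dropped:
                assert acc not in db.proteins
                continue
            region = truth.mispredicted.get(acc, (0, -1))
            diff = [
                (i + 1, seq[i], db.proteins[acc][i])
                for i in range(len(seq))
                if seq[i] != db.proteins[acc][i]
                and not (region[0] <= i + 1 <= region[1])
            ]
            assert diff == truth.substitutions.get(acc, [])
        for subs in truth.substitutions.values():
            for _pos, t_aa, d_aa in subs:
                assert collapse_il(t_aa) != collapse_il(d_aa)

    def test_substitution_count_within_three_sd_of_binomial(self):
        # 10 proteins x 300 residues at 1 SAP / 100 residues: Bin(3000, 0.01)
        config = SimulationConfig(
            n_proteins=10,
            protein_length_range=(300, 300),
            divergence_per_db=(1.0,),
            db_labels=("sister",),
            drop_fraction=0.0,
            mispredict_fraction=0.0,
            seed=6,
        )
        target = generate_reference_proteome(config)
        _, truth = evolve_proteome(target, 0, config)
        expected, sd = 30.0, math.sqrt(3000 * 0.01 * 0.99)
        assert abs(truth.n_substitutions() - expected) < 3 * sd

    def test_excessive_divergence_rejected(self):
        config = SimulationConfig(
            n_proteins=2, divergence_per_db=(150.0,), db_labels=("x",), seed=7
        )
        target = generate_reference_proteome(config)
        with pytest.raises(SimulationConfigError):
            evolve_proteome(target, 0, config)

    def test_clustering_inflates_per_window_variance(self):
        base = dict(
            n_proteins=30,
            protein_length_range=(300, 300),
            divergence_per_db=(5.0,),
            db_labels=("sister",),
            drop_fraction=0.0,
            mispredict_fraction=0.0,
            seed=8,
        )
        window = 10

        def window_variance(clustering_weight):
            config = SimulationConfig(clustering_weight=clustering_weight, **base)
            target = generate_reference_proteome(config)
            _, truth = evolve_proteome(target, 0, config)
            counts = []
            for acc, seq in target.proteins.items():
                per_window = np.zeros(len(seq) // window)
                for pos, _t, _d in truth.substitutions.get(acc, []):
                    w = (pos - 1) // window
                    if w < len(per_window):
                        per_window[w] += 1
                counts.extend(per_window)
            return np.var(counts)

        assert window_variance(25.0) > window_variance(0.0)

    def test_truth_rejects_silent_entries(self):
        with pytest.raises(ValueError):
            OrthologTruth("a", "b", substitutions={"P1": [(3, "A", "A")]})


class TestSimulateSearch:
    def saturated_config(self, **kwargs):
        model = IdentificationModel(
            base_logit=60.0, length_coefficient=0.0, sap_coefficient=0.0
        )
        defaults = dict(
            n_proteins=5,
            protein_length_range=(80, 120),
            divergence_per_db=(3.0,),
            db_labels=("sister",),
            drop_fraction=0.0,
            mispredict_fraction=0.0,
            n_individuals=1,
            files_per_individual=1,
            id_model=model,
            seed=9,
        )
        defaults.update(kwargs)
        return SimulationConfig(**defaults)

    def test_saturated_model_identifies_all_low_sap_peptides(self):
        config = self.saturated_config()
        target = generate_reference_proteome(config)
        db, truth = evolve_proteome(target, 0, config)
        psms = simulate_search(target, db, truth, config)
        universe = simulate_search(target, target, None, config)
        # every scan with <= 2 SAPs must be identified in the cross search
        identified = set(psms["scan_id"])
        by_scan = dict(zip(universe["scan_id"], zip(universe["accession"],
                                                    universe["start"],
                                                    universe["end"])))
        for scan, (acc, start, end) in by_scan.items():
            sm = truth.site_map(acc, len(target.proteins[acc]))
            n = len(sm.substitutions_in(start, end))
            assert (scan in identified) == (n <= 2)

    def test_three_sap_peptides_never_identified(self):
        # plant 3 SAPs inside one tryptic peptide of a hand-built protein
        target = ReferenceProteome(
            taxon="t", proteins={"P1": "MKAAACDDEEFFGGHHK" + "WYSTV"}
        )
        db, truth = apply_substitutions(
            target, {"P1": [(5, "W"), (8, "Y"), (11, "T")]}, "sister"
        )
        config = self.saturated_config(n_proteins=1)
        psms = simulate_search(target, db, truth, config)
        assert not ((psms["accession"] == "P1") & (psms["start"] == 3)).any()

    def test_identified_fraction_matches_binomial_at_half(self):
        # base_logit 0 with zero coefficients: p = 0.5 for every peptide
        model = IdentificationModel(
            base_logit=0.0, length_coefficient=0.0, sap_coefficient=0.0
        )
        config = SimulationConfig(
            n_proteins=30,
            protein_length_range=(300, 300),
            divergence_per_db=(1.0,),
            db_labels=("sister",),
            drop_fraction=0.0,
            mispredict_fraction=0.0,
            n_individuals=2,
            files_per_individual=2,
            id_model=model,
            seed=10,
        )
        import dataclasses

        target = generate_reference_proteome(config)
        saturated = dataclasses.replace(
            config,
            id_model=IdentificationModel(
                base_logit=60.0, length_coefficient=0.0, sap_coefficient=0.0
            ),
        )
        universe = simulate_search(target, target, None, saturated)
        psms = simulate_search(target, target, None, config)
        n_trials = len(universe)
        frac = len(psms) / n_trials
        sd = math.sqrt(0.25 / n_trials)
        assert abs(frac - 0.5) < 3 * sd

    def test_determinism_and_shared_scan_ids(self):
        config = self.saturated_config(n_individuals=2)
        target = generate_reference_proteome(config)
        db, truth = evolve_proteome(target, 0, config)
        a = simulate_search(target, db, truth, config)
        b = simulate_search(target, db, truth, config)
        pd.testing.assert_frame_equal(a, b)
        s1 = simulate_search(target, target, None, config)
        # same scan id refers to the same peptide span in both searches
        merged = a.merge(s1, on=["dataset_id", "scan_id"], suffixes=("_x", "_s1"))
        assert (merged["accession_x"] == merged["accession_s1"]).all()
        assert (merged["start_x"] == merged["start_s1"]).all()

    def test_truth_database_mismatch_rejected(self):
        config = self.saturated_config()
        target = generate_reference_proteome(config)
        db, truth = evolve_proteome(target, 0, config)
        other = ReferenceProteome(taxon="other", proteins=dict(db.proteins))
        with pytest.raises(ValueError):
            simulate_search(target, other, truth, config)

    def test_identification_odds_monotone_in_sap_count(self):
        # checked on the exact model expectation, not a noisy draw; raising
        # the distance of any given peptide never helps identification, and
        # the SAP cap zeroes everything beyond two substitutions
        model = IdentificationModel()
        config = SimulationConfig(
            n_proteins=20,
            protein_length_range=(200, 300),
            drop_fraction=0.0,
            mispredict_fraction=0.0,
            seed=11,
        )
        target = generate_reference_proteome(config)
        from paleosap.sim import digest_proteome

        lengths = np.array([s.length for s in digest_proteome(target, config)])
        rates = [float(np.mean(model.p_identified(lengths, k))) for k in (1, 2, 3, 5)]
        assert rates[0] > rates[1] > rates[2] == rates[3] == 0.0
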