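"""The staged estimation protocol: steps, averaging, consistency, corrections."""

from __future__ import annotations

import pytest

from wolfped.error_model import ErrorRates
from wolfped.genodata import AlleleFrequencyTable
from wolfped.pedigree_core import UNKNOWN, UNSAMPLED, Pedigree, is_legal
from wolfped.protocol import (
    CorrectionsLedger,
    ModalRun,
    ProtocolConfig,
    StudyData,
    apply_corrections,
    step1_preliminary,
    step2_error_rates,
    step5_average,
    step6_consistency,
)


def _informative_freqs(n=8):
    return AlleleFrequencyTable(
        {f"l{i}": {a: 0.25 for a in "ABCD"} for i in range(n)}
    )


def _family_data():
    freqs = _informative_freqs()
    genos = {
        "mum": {f"l{i}": ("A", "A") for i in range(8)},
        "dad": {f"l{i}": ("C", "C") for i in range(8)},
        "cub1": {f"l{i}": ("A", "C") for i in range(8)},
        "cub2": {f"l{i}": ("A", "C") for i in range(8)},
    }
    sexes = {"mum": "F", "dad": "M", "cub1": "F", "cub2": "M"}
    from datetime import date

    dates = {"mum": date(2010, 1, 1), "dad": date(2010, 2, 1),
             "cub1": date(2013, 5, 1), "cub2": date(2013, 6, 1)}
    return StudyData(genotypes=genos, sexes=sexes, freqs=freqs, detection_dates=dates)


def _micro_config():
    return ProtocolConfig(
        step1_iterations=1500, step1_burn_in=300,
        step2_iterations=400, step2_burn_in=100,
        step3_runs=2, step3_iterations=800, step3_burn_in=150,
        step4_runs=2, step4_iterations=800, step4_burn_in=150,
    )


class TestStep1:
    def test_unique_compatible_parents_confident(self):
        data = _family_data()
        cfg = _micro_config()
        cfg.step1_e1 = cfg.step1_e2 = 1e-6
        modal, partial, post = step1_preliminary(data, cfg, seed=4)
        for cub in ("cub1", "cub2"):
            assert modal.parents[cub] == ("mum", "dad")
            dp, sp = modal.link_prob[cub]
            assert dp > 0.9 and sp > 0.9
            assert partial.parents[cub] == ("mum", "dad")

    def test_no_candidates_assigns_unsampled(self):
        freqs = _informative_freqs(2)
        data = StudyData(
            genotypes={"only": {"l0": ("A", "B"), "l1": ("C", "D")}},
            sexes={"only": "F"},
            freqs=freqs,
        )
        modal, _, _ = step1_preliminary(data, _micro_config(), seed=1)
        assert modal.parents["only"] == (UNSAMPLED, UNSAMPLED)


class TestStep2:
    def test_partial_pedigree_informs_rates(self):
        data = _family_data()
        # perfectly concordant triplicates over several samples each
        data.replicate_states = {
            f"{ind}-s{k}": {loc: [g] * 3 for loc, g in geno.items()}
            for ind, geno in data.genotypes.items()
            for k in range(8)
        }
        data.sample_to_individual = {
            sid: sid.split("-")[0] for sid in data.replicate_states
        }
        partial = Pedigree(
            parents={"cub1": ("mum", "dad"), "cub2": ("mum", "dad")},
            sexes=data.sexes,
        )
        rates, summaries = step2_error_rates(data, partial, _micro_config(), seed=2)
        for loc in data.freqs.loci:
            e1, e2 = rates.get(loc, "SCAT")
            assert e1 < 4 / 104  # shrunk below the prior mean
            # tissue class keeps its constants
            assert rates.get(loc, "TISSUE_SECRETION") == (0.04, 0.022)


def _run(parents, support, dam_marg=None, sire_marg=None):
    ped = Pedigree(parents=dict(parents))
    dm = dam_marg or {o: {p[0]: 1.0} for o, p in parents.items()}
    sm = sire_marg or {o: {p[1]: 1.0} for o, p in parents.items()}
    return ModalRun(ped, dict(support), dm, sm)


class TestStep5Averaging:
    def test_higher_mean_support_wins(self):
        runs = [
            _run({"o": ("d1", "s1")}, {"o": 0.8}),
            _run({"o": ("d1", "s1")}, {"o": 0.8}),
            _run({"o": ("d2", "s2")}, {"o": 0.3}),
        ]
        main = step5_average(runs)
        assert main.parents["o"] == ("d1", "s1")

    def test_absent_run_counts_zero(self):
        # pair at 0.9 in half the runs loses to 0.5 in all runs
        runs = []
        for k in range(10):
            runs.append(_run({"o": ("dA", "sA")}, {"o": 0.9}))
        for k in range(10):
            runs.append(_run({"o": ("dB", "sB")}, {"o": 0.5}))
        # pair A mean = 0.45, pair B mean = 0.25 -> A wins; but with
        # 20/20 at 0.5 vs 10/20 at 0.9 the consistent pair must win
        runs_b = [_run({"o": ("dB", "sB")}, {"o": 0.5}) for _ in range(20)]
        runs_mixed = runs[:10] + runs_b[:10]
        main = step5_average(runs_mixed)
        # A: 10 * 0.9 / 20 = 0.45 ; B: 10 * 0.5 / 20 = 0.25
        assert main.parents["o"] == ("dA", "sA")
        runs_mixed2 = [_run({"o": ("dA", "sA")}, {"o": 0.9})] * 10 + runs_b
        # now B appears 20/20: A 10*0.9/30 = 0.3 < B 20*0.5/30 = 0.33
        main2 = step5_average(runs_mixed2)
        assert main2.parents["o"] == ("dB", "sB")

    def test_idempotent_on_identical_runs(self):
        runs = [_run({"o": ("d", "s")}, {"o": 0.7})] * 5
        a = step5_average(runs)
        b = step5_average(runs)
        assert a.parents == b.parents and a.link_prob == b.link_prob

    def test_tie_breaks_toward_unsampled(self):
        runs = [
            _run({"o": ("d", "s")}, {"o": 0.5}),
            _run({"o": (UNSAMPLED, UNSAMPLED)}, {"o": 0.5}),
        ]
        main = step5_average(runs)
        assert main.parents["o"] == (UNSAMPLED, UNSAMPLED)


class TestStep6:
    def test_anachronism_flagged(self):
        ped = Pedigree(
            parents={"p": (UNSAMPLED, UNSAMPLED), "o": ("p", UNSAMPLED)},
            sexes={"p": "F"},
            link_prob={"o": (0.95, 0.95), "p": (0.9, 0.9)},
        )
        report = step6_consistency(
            ped, detection_dates={"p": 2014, "o": 2015}
        )
        assert report.anachronisms  # parent aged 1 at offspring birth

    def test_single_offspring_medium_pair_flagged(self):
        ped = Pedigree(
            parents={"o": ("d", "s"), "d": (UNSAMPLED, UNSAMPLED), "s": (UNSAMPLED, UNSAMPLED)},
            link_prob={"o": (0.75, 0.75), "d": (0.9, 0.9), "s": (0.9, 0.9)},
            sexes={"d": "F", "s": "M"},
        )
        report = step6_consistency(ped, detection_dates={"o": 2015, "d": 2010, "s": 2010})
        assert report.single_offspring_pairs

    def test_multi_offspring_pair_not_flagged(self):
        ped = Pedigree(
            parents={"o1": ("d", "s"), "o2": ("d", "s")},
            link_prob={"o1": (0.75, 0.75), "o2": (0.96, 0.96)},
            sexes={"d": "F", "s": "M"},
        )
        report = step6_consistency(ped, detection_dates={"o1": 2015, "o2": 2015, "d": 2010, "s": 2010})
        assert not report.single_offspring_pairs

    def test_territory_conflict(self):
        ped = Pedigree(
            parents={"o1": ("d1", "s1"), "o2": ("d2", "s2")},
            link_prob={"o1": (0.9, 0.9), "o2": (0.9, 0.9)},
        )
        report = step6_consistency(
            ped,
            detection_dates={"o1": 2015, "o2": 2015, "d1": 2010, "s1": 2010,
                             "d2": 2010, "s2": 2010},
            territories={"o1": ("pack-A", 2015), "o2": ("pack-A", 2015)},
        )
        assert report.territory_conflicts

    def test_counts_partition_individuals(self):
        ped = Pedigree(
            parents={
                "a": ("d", "s"), "b": ("d", UNKNOWN), "c": (UNKNOWN, "s"),
                "e": (UNKNOWN, UNKNOWN),
            },
            link_prob={"a": (0.9, 0.9), "b": (0.9, 0.0), "c": (0.0, 0.9), "e": (0.0, 0.0)},
            sexes={"d": "F", "s": "M"},
        )
        report = step6_consistency(ped, detection_dates={})
        assert report.counts == {"both": 1, "only_mother": 1, "only_father": 1, "neither": 1}
        assert sum(report.counts.values()) == len(ped.parents)


class TestCorrections:
    def _ped(self):
        return Pedigree(
            parents={"o": ("d1", "s1"), "d1": (UNSAMPLED, UNSAMPLED),
                     "s1": (UNSAMPLED, UNSAMPLED), "d2": (UNSAMPLED, UNSAMPLED)},
            sexes={"d1": "F", "d2": "F", "s1": "M", "o": "F"},
        )

    def test_empty_ledger_is_identity(self):
        ped = self._ped()
        out, summary = apply_corrections(ped, CorrectionsLedger())
        assert out.parents == ped.parents
        assert summary == {"altered": 0, "confirmed": 0}

    def test_single_reassignment(self):
        ledger = CorrectionsLedger()
        ledger.add("o", "dam", "d1", "d2", "TERRITORY_CONFLICT", "pack B pair")
        out, summary = apply_corrections(self._ped(), ledger)
        assert out.parents["o"] == ("d2", "s1")
        assert summary["altered"] == 1

    def test_confirmation_changes_nothing(self):
        ledger = CorrectionsLedger()
        ledger.add("o", "dam", "d1", "d1", "CONFIRMED", "ok")
        out, summary = apply_corrections(self._ped(), ledger)
        assert out.parents == self._ped().parents
        assert summary == {"altered": 0, "confirmed": 1}

    def test_cycle_creating_edit_rejected(self):
        ped = Pedigree(
            parents={"a": ("b", UNSAMPLED), "b": (UNKNOWN, UNSAMPLED)},
            sexes={"b": "F", "a": "F"},
        )
        ledger = CorrectionsLedger()
        ledger.add("b", "dam", "UNKNOWN", "a", "ANACHRONISM", "own grandparent")
        with pytest.raises(ValueError, match="rejected"):
            apply_corrections(ped, ledger)

    def test_stale_old_value_rejected(self):
        ledger = CorrectionsLedger()
        ledger.add("o", "dam", "dX", "d2", "ANACHRONISM", "")
        with pytest.raises(ValueError, match="expected"):
            apply_corrections(self._ped(), ledger)

    def test_unknown_reason_rejected(self):
        with pytest.raises(ValueError):
            CorrectionsLedger().add("o", "dam", "a", "b", "WHIM", "")


class TestConfig:
    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ProtocolConfig(confident=1.5)
        with pytest.raises(ValueError):
            ProtocolConfig(step3_runs=0)

    def test_desk_scale_keeps_scientific_constants(self):
        full, desk = ProtocolConfig(), ProtocolConfig.desk_scale()
        assert (desk.step1_e1, desk.step1_e2) == (full.step1_e1, full.step1_e2)
        assert desk.confident == full.confident
        assert desk.breeder_min_mean == full.breeder_min_mean
        assert desk.priors == full.priors
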