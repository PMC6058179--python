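"""Adaptive testing engine: selection, stopping, sessions, batches."""

import numpy as np
import pytest

from depcat import (CatConfig, CatSimulator, CatTrace, PopulationSpec,
                    ResponseMatrix, eap_batch,
                    item_information, select_first_item,
                    select_next_item_mfi, should_stop, simulate_responses,
                    simulate_thetas)
from depcat.bank import ItemBank, ItemParameters


@pytest.fixture(scope="module")
def small_batch(table4_bank):
    thetas, _ = simulate_thetas(PopulationSpec(20, seed=61))
    return simulate_responses(table4_bank, thetas, seed=62)


class TestFirstItem:
    def test_seeded_choice_is_reproducible(self, table4_bank):
        picks = {select_first_item(table4_bank,
                                   np.random.default_rng(99))
                 for _ in range(5)}
        assert len(picks) == 1

    def test_uniform_over_the_bank(self, table4_bank):
        rng = np.random.default_rng(7)
        n = 10_000
        counts = {}
        for _ in range(n):
            iid = select_first_item(table4_bank, rng)
            counts[iid] = counts.get(iid, 0) + 1
        p = 1.0 / 68
        bound = 4 * np.sqrt(n * p * (1 - p))
        for iid in table4_bank.item_ids:
            assert abs(counts.get(iid, 0) - n * p) < bound

    def test_single_item_bank_forced(self):
        bank = ItemBank([ItemParameters("only", "GRM", 4, a=1.0,
                                        b=(0.0, 0.5, 1.0))])
        assert select_first_item(bank, np.random.default_rng(0)) == "only"

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            select_first_item(ItemBank([]), np.random.default_rng(0))


class TestMfiSelection:
    def test_matches_exhaustive_argmax_oracle(self, table4_bank):
        rng = np.random.default_rng(71)
        for _ in range(25):
            administered = list(rng.choice(table4_bank.item_ids,
                                           size=rng.integers(0, 60),
                                           replace=False))
            theta = float(rng.normal())
            chosen = select_next_item_mfi(table4_bank, administered, theta)
            remaining = [i for i in table4_bank.item_ids
                         if i not in set(administered)]
            infos = {i: item_information(
                table4_bank.items[table4_bank.index_of(i)], theta)
                for i in remaining}
            assert infos[chosen] == max(infos.values())

    def test_exact_ties_break_to_lower_index(self):
        dup = ItemParameters("A", "GRM", 4, a=1.5, b=(-0.5, 0.5, 1.5))
        dup2 = ItemParameters("B", "GRM", 4, a=1.5, b=(-0.5, 0.5, 1.5))
        bank = ItemBank([dup, dup2])
        assert select_next_item_mfi(bank, [], 0.0) == "A"

    def test_all_administered_rejected(self, table4_bank):
        with pytest.raises(ValueError):
            select_next_item_mfi(table4_bank, table4_bank.item_ids, 0.0)


class TestStopping:
    @staticmethod
    def _trace(se, n=1):
        tr = CatTrace("r")
        tr.item_ids = [str(i) for i in range(n)]
        tr.responses = [0] * n
        tr.thetas = [0.0] * n
        tr.ses = [1.0] * (n - 1) + [se]
        return tr

    def test_precision_reached(self, table4_bank):
        stop, reason = should_stop(self._trace(0.19), CatConfig(0.2),
                                   table4_bank)
        assert stop and reason == "se_met"

    def test_no_rule_continues_until_bank_exhausted(self, table4_bank):
        tr = self._trace(0.5, n=67)
        tr.item_ids = table4_bank.item_ids[:67]
        stop, _ = should_stop(tr, CatConfig(stopping_se=None), table4_bank)
        assert not stop
        tr2 = self._trace(0.5, n=68)
        tr2.item_ids = table4_bank.item_ids
        stop, reason = should_stop(tr2, CatConfig(stopping_se=None),
                                   table4_bank)
        assert stop and reason == "bank_exhausted"

    def test_unreachable_precision_exhausts_bank(self, table4_bank):
        tr = self._trace(0.21, n=68)
        tr.item_ids = table4_bank.item_ids
        stop, reason = should_stop(tr, CatConfig(0.2), table4_bank)
        assert stop and reason == "bank_exhausted"

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CatConfig(stopping_se=-0.1)
        with pytest.raises(ValueError):
            CatConfig(max_items=0)


class TestSession:
    def test_no_stop_administers_full_bank_and_matches_full_eap(
            self, table4_bank, small_batch, grid):
        sim = CatSimulator(table4_bank, CatConfig(stopping_se=None, seed=5))
        trace = sim.run_session(small_batch.data[0])
        assert trace.n_administered == 68
        assert trace.stop_reason == "bank_exhausted"
        from depcat import eap_estimate
        full_theta, _ = eap_batch(small_batch, table4_bank.items, grid)
        single, _ = eap_estimate(small_batch.data[0], table4_bank.items,
                                 grid)
        assert trace.final_theta == single           # same grid: exact
        assert trace.final_theta == pytest.approx(full_theta[0], abs=1e-12)

    def test_all_lowest_responses_drive_theta_down(self, table4_bank):
        sim = CatSimulator(table4_bank, CatConfig(stopping_se=None, seed=5))
        trace = sim.run_session(np.zeros(68, dtype=int))
        assert trace.final_theta < 0
        assert np.all(np.diff(trace.thetas) <= 1e-9)

    def test_identical_inputs_give_bit_identical_traces(self, table4_bank,
                                                        small_batch):
        sim = CatSimulator(table4_bank, CatConfig(stopping_se=0.3, seed=9))
        t1 = sim.run_session(small_batch.data[3], respondent_id="x")
        t2 = sim.run_session(small_batch.data[3], respondent_id="x")
        assert t1.item_ids == t2.item_ids
        assert t1.thetas == t2.thetas
        assert t1.ses == t2.ses

    def test_se_met_invariant(self, table4_bank, small_batch):
        sim = CatSimulator(table4_bank, CatConfig(stopping_se=0.4, seed=9))
        for i in range(small_batch.n_respondents):
            tr = sim.run_session(small_batch.data[i], respondent_id=str(i))
            assert len(tr.thetas) == len(tr.item_ids) == len(tr.ses)
            if tr.stop_reason == "se_met":
                assert tr.final_se <= 0.4

    def test_items_used_monotone_in_stopping_threshold(self, table4_bank,
                                                       small_batch):
        counts = []
        for se in (0.6, 0.5, 0.4, 0.3, 0.2, None):
            sim = CatSimulator(table4_bank,
                               CatConfig(stopping_se=se, seed=13))
            tr = sim.run_session(small_batch.data[1], respondent_id="m")
            counts.append(tr.n_administered)
        assert counts == sorted(counts)
        assert counts[-1] == 68

    def test_missing_response_skipped_with_flag(self, table4_bank):
        responses = np.ones(68, dtype=float)
        sim0 = CatSimulator(table4_bank, CatConfig(stopping_se=None, seed=3))
        first = sim0.run_session(responses).item_ids[0]
        responses[table4_bank.index_of(first)] = np.nan
        tr = sim0.run_session(responses)
        assert f"missing_response:{first}" in tr.flags
        assert first not in tr.item_ids
        assert tr.n_administered == 67

    def test_generative_mode_tracks_true_theta(self, table4_bank):
        sim = CatSimulator(table4_bank, CatConfig(stopping_se=0.3, seed=21))
        trace = sim.run_session(None, respondent_id="g", true_theta=1.5)
        assert trace.stop_reason in ("se_met", "bank_exhausted")
        assert abs(trace.final_theta - 1.5) < 1.0

    def test_max_items_cap(self, table4_bank, small_batch):
        sim = CatSimulator(table4_bank,
                           CatConfig(stopping_se=0.01, max_items=5, seed=2))
        tr = sim.run_session(small_batch.data[0])
        assert tr.n_administered == 5
        assert tr.stop_reason == "max_items"


class TestBatch:
    def test_batch_equals_looped_sessions(self, table4_bank, small_batch):
        cfg = CatConfig(stopping_se=0.3, seed=17)
        sim = CatSimulator(table4_bank, cfg)
        traces = sim.run_batch(small_batch)
        assert len(traces) == small_batch.n_respondents
        for i, rid in enumerate(small_batch.respondent_ids[:5]):
            solo = sim.run_session(small_batch.data[i], respondent_id=rid)
            assert solo.item_ids == traces[i].item_ids
            assert solo.thetas == traces[i].thetas

    def test_permuting_respondents_permutes_but_preserves_traces(
            self, table4_bank, small_batch):
        cfg = CatConfig(stopping_se=0.3, seed=17)
        sim = CatSimulator(table4_bank, cfg)
        base = {t.respondent_id: t for t in sim.run_batch(small_batch)}
        perm = np.random.default_rng(1).permutation(
            small_batch.n_respondents)
        shuffled = ResponseMatrix(
            small_batch.data[perm],
            respondent_ids=[small_batch.respondent_ids[i] for i in perm],
            item_ids=small_batch.item_ids)
        for t in sim.run_batch(shuffled):
            assert t.item_ids == base[t.respondent_id].item_ids
            assert t.thetas == base[t.respondent_id].thetas
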