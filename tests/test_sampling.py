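"""Piece partitioning, chunk sampling, blinding, and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethochunk import (
    SamplingParams,
    build_presentation,
    partition_pieces,
    read_plan,
    read_schedule,
    sample_chunks,
    unblind,
    write_plan,
    write_schedule,
)
from ethochunk.errors import ValidationError


class TestSamplingParams:
    def test_defaults_score_300_seconds(self):
        params = SamplingParams()
        assert params.scored_duration_s == 300.0
        assert params.slots_per_piece == 60

    def test_too_many_chunks_per_piece_rejected(self):
        with pytest.raises(ValidationError, match="slots"):
            SamplingParams(piece_dur_s=90, chunk_dur_s=10, chunks_per_piece=10)


class TestPartitionPieces:
    def test_default_three_ten_minute_pieces(self):
        windows = partition_pieces(1800.0, SamplingParams())
        assert windows == [(0.0, 600.0), (600.0, 1200.0), (1200.0, 1800.0)]

    def test_single_piece_mode_nullifies_stratification(self):
        params = SamplingParams(pieces_n=1, piece_dur_s=600.0)
        assert partition_pieces(600.0, params) == [(0.0, 600.0)]

    def test_too_short_recording_states_required_minimum(self):
        with pytest.raises(ValidationError, match="1800"):
            partition_pieces(1799.0, SamplingParams())

    def test_trailing_remainder_excluded_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="ethochunk.sampling"):
            windows = partition_pieces(1812.5, SamplingParams())
        assert windows[-1] == (1200.0, 1800.0)
        assert any("12.5" in rec.getMessage() for rec in caplog.records)


class TestSampleChunks:
    def test_default_plan_shape(self):
        plan = sample_chunks("vid", 1800.0, SamplingParams(master_seed=7))
        assert len(plan.chunks) == 30
        per_piece = {pi: sum(c.piece_index == pi for c in plan.chunks) for pi in range(3)}
        assert per_piece == {0: 10, 1: 10, 2: 10}
        assert plan.scored_duration_s == 300.0

    def test_chunks_lie_on_slot_grid_within_their_piece(self):
        params = SamplingParams(master_seed=3)
        plan = sample_chunks("vid", 1800.0, params)
        for c in plan.chunks:
            offset = c.start_s - c.piece_index * params.piece_dur_s
            assert 0 <= offset < params.piece_dur_s
            assert offset % params.chunk_dur_s == 0
            assert c.start_s + c.dur_s <= (c.piece_index + 1) * params.piece_dur_s

    def test_saturated_piece_uses_every_slot(self):
        params = SamplingParams(pieces_n=1, piece_dur_s=100, chunk_dur_s=10,
                                chunks_per_piece=10, master_seed=11)
        plan = sample_chunks("vid", 100.0, params)
        assert sorted(c.start_s for c in plan.chunks) == [float(10 * i) for i in range(10)]

    def test_identical_seed_reproduces_identical_plan(self):
        a = sample_chunks("vid", 1800.0, SamplingParams(master_seed=5))
        b = sample_chunks("vid", 1800.0, SamplingParams(master_seed=5))
        assert a == b

    def test_adding_a_video_never_perturbs_another(self):
        # substreams are keyed by (seed, video_id, piece); a second video's
        # presence cannot change the first video's plan
        alone = sample_chunks("vid-a", 1800.0, SamplingParams(master_seed=5))
        _other = sample_chunks("vid-b", 1800.0, SamplingParams(master_seed=5))
        again = sample_chunks("vid-a", 1800.0, SamplingParams(master_seed=5))
        assert alone == again

    @given(seed=st.integers(0, 2**31 - 1), vid=st.sampled_from(["a", "b", "cage-7"]))
    @settings(max_examples=50)
    def test_plans_always_nonoverlapping_and_balanced(self, seed, vid):
        plan = sample_chunks(vid, 1800.0, SamplingParams(master_seed=seed))
        ordered = sorted(plan.chunks, key=lambda c: c.start_s)
        assert all(b.start_s >= a.start_s + a.dur_s for a, b in zip(ordered, ordered[1:]))
        counts = [sum(c.piece_index == pi for c in plan.chunks) for pi in range(3)]
        assert counts == [10, 10, 10]

    def test_slot_frequencies_consistent_with_uniform_draw(self):
        """Over many seeds every slot of a piece is picked ~ k/slots of the time."""
        n_seeds = 2000
        params_proto = dict(pieces_n=1, piece_dur_s=600.0, chunks_per_piece=10,
                            chunk_dur_s=10.0)
        counts = np.zeros(60)
        for seed in range(n_seeds):
            plan = sample_chunks("vid", 600.0,
                                 SamplingParams(master_seed=seed, **params_proto))
            for c in plan.chunks:
                counts[int(c.start_s // 10)] += 1
        p = 10 / 60
        sigma = np.sqrt(n_seeds * p * (1 - p))
        assert np.all(np.abs(counts - n_seeds * p) < 4 * sigma)


class TestPresentation:
    def _plans(self, n=6, seed=1):
        return [sample_chunks(f"v{i}", 1800.0, SamplingParams(master_seed=seed))
                for i in range(n)]

    def test_pooled_schedule_is_a_permutation_of_all_chunks(self):
        plans = self._plans()
        schedule = build_presentation(plans, seed=9)
        assert len(schedule) == 180
        refs = {it.chunk_ref for it in schedule.items}
        expected = {(p.video_id, c.chunk_id) for p in plans for c in p.chunks}
        assert refs == expected
        assert [it.presentation_rank for it in schedule.items] == list(range(180))

    def test_single_chunk_schedule(self):
        params = SamplingParams(pieces_n=1, piece_dur_s=10, chunks_per_piece=1,
                                chunk_dur_s=10, master_seed=0)
        plan = sample_chunks("v", 10.0, params)
        schedule = build_presentation([plan], seed=0)
        assert len(schedule) == 1
        assert schedule.items[0].presentation_rank == 0

    def test_duplicate_chunk_reference_rejected(self):
        plan = self._plans(1)[0]
        with pytest.raises(ValidationError, match="duplicate"):
            build_presentation([plan, plan], seed=0)

    def test_blind_codes_are_opaque_and_unique(self):
        schedule = build_presentation(self._plans(), seed=4)
        codes = [it.blind_code for it in schedule.items]
        assert len(set(codes)) == len(codes)
        for code, it in zip(codes, schedule.items):
            vid, chunk_id = it.chunk_ref
            assert vid not in code and chunk_id not in code

    def test_mean_presentation_rank_is_uniform_over_seeds(self):
        """Each chunk's mean rank over repeated seeds ~ (N-1)/2."""
        params = SamplingParams(pieces_n=1, piece_dur_s=100, chunk_dur_s=10,
                                chunks_per_piece=10, master_seed=0)
        plans = [sample_chunks(f"v{i}", 100.0, params) for i in range(2)]
        n_items = 20
        n_rep = 600
        rank_sums = {}
        for seed in range(n_rep):
            schedule = build_presentation(plans, seed=seed)
            for it in schedule.items:
                rank_sums[it.chunk_ref] = rank_sums.get(it.chunk_ref, 0) + it.presentation_rank
        expected = (n_items - 1) / 2
        sd_mean = np.sqrt((n_items**2 - 1) / 12 / n_rep)
        for ref, total in rank_sums.items():
            assert abs(total / n_rep - expected) < 4.5 * sd_mean

    def test_unblind_inverts_blinding_exactly(self):
        schedule = build_presentation(self._plans(2), seed=3)
        scores = {it.blind_code: i for i, it in enumerate(schedule.items)}
        unblinded = unblind(schedule, scores)
        assert len(unblinded) == 60
        for it in schedule.items:
            assert unblinded[it.chunk_ref] == scores[it.blind_code]

    def test_unblind_rejects_stale_codes(self):
        schedule = build_presentation(self._plans(1), seed=3)
        with pytest.raises(ValidationError, match="STALE0"):
            unblind(schedule, {"STALE0": 1})


class TestFileRoundTrip:
    def test_plan_round_trip(self, tmp_path):
        plan = sample_chunks("vid", 1800.0, SamplingParams(master_seed=2))
        path = tmp_path / "plan.csv"
        write_plan(plan, path)
        back = read_plan(path)
        assert back.video_id == plan.video_id
        assert back.chunks == plan.chunks

    def test_scorer_facing_schedule_withholds_video_identity(self, tmp_path):
        plans = [sample_chunks(f"secret-video-{i}", 1800.0,
                               SamplingParams(master_seed=2)) for i in range(2)]
        schedule = build_presentation(plans, seed=1)
        sched_path = tmp_path / "schedule.csv"
        map_path = tmp_path / "blind_map.csv"
        write_schedule(schedule, sched_path, map_path)
        scorer_text = sched_path.read_text()
        assert scorer_text.splitlines()[0] == "presentation_rank,blind_code,dur_s"
        assert "secret-video" not in scorer_text
        assert "secret-video" in map_path.read_text()

    def test_schedule_round_trip(self, tmp_path):
        plans = [sample_chunks(f"v{i}", 1800.0, SamplingParams(master_seed=2))
                 for i in range(2)]
        schedule = build_presentation(plans, seed=1)
        write_schedule(schedule, tmp_path / "s.csv", tmp_path / "m.csv")
        back = read_schedule(tmp_path / "s.csv", tmp_path / "m.csv", plans=plans)
        assert back.items == schedule.items

    def test_reading_overlapping_plan_is_a_validation_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "video_id,chunk_id,piece_index,start_s,dur_s\n"
            "v,c1,0,0.000,10.000\n"
            "v,c2,0,5.000,10.000\n")
        with pytest.raises(ValidationError, match="overlap"):
            read_plan(path)

    def test_byte_identical_outputs_for_identical_inputs(self, tmp_path):
        for trial in ("a", "b"):
            d = tmp_path / trial
            d.mkdir()
            plans = [sample_chunks(f"v{i}", 1800.0, SamplingParams(master_seed=6))
                     for i in range(3)]
            for i, plan in enumerate(plans):
                write_plan(plan, d / f"plan{i}.csv")
            write_schedule(build_presentation(plans, seed=6),
                           d / "schedule.csv", d / "blind_map.csv")
        for name in ["plan0.csv", "plan1.csv", "plan2.csv", "schedule.csv",
                     "blind_map.csv"]:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
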