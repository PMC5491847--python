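import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sg

from emgsynergy import (CoherenceConfig, FilterBank, SynergyFilterConfig, TaskSignal,
                        apply_filterbank, build_subject_filters, design_bandstop,
                        exclusion_rule, merge_bands)
from emgsynergy.coherence import FrequencyBand
from emgsynergy.filters import steady_phase
from emgsynergy.simulate import ProtocolSpec, SubjectProfile, generate_session

FS = 1000.0


def B(lo, hi):
    return FrequencyBand(lo, hi)


def lattice_union(per_task, step=0.1):
    """Brute-force union oracle on a 0.1-Hz lattice."""
    grid = np.arange(0.5, 100.0, step)
    covered = np.zeros(grid.size, bool)
    for bands in per_task.values():
        for b in bands:
            covered |= (grid >= b.lo_hz - step / 4) & (grid <= b.hi_hz + step / 4)
    out, i = [], 0
    while i < grid.size:
        if covered[i]:
            j = i
            while j + 1 < grid.size and covered[j + 1]:
                j += 1
            out.append((grid[i], grid[j]))
            i = j + 1
        else:
            i += 1
    return out


class TestMergeBands:
    def test_overlapping_bands_coalesce_across_tasks(self):
        merged = merge_bands({"grasp": [B(8, 11)], "open": [B(10, 13)], "relax": []})
        assert merged == [B(8.0, 13.0)]

    def test_all_empty_gives_empty(self):
        assert merge_bands({"grasp": [], "open": [], "relax": []}) == []

    def test_disjoint_bands_sorted(self):
        merged = merge_bands({"grasp": [B(12, 13)], "open": [B(8, 9)]})
        assert merged == [B(8.0, 9.0), B(12.0, 13.0)]

    def test_abutting_bands_coalesce(self):
        assert merge_bands({"a": [B(8, 10)], "b": [B(10, 12)]}) == [B(8.0, 12.0)]

    @given(st.lists(st.tuples(st.floats(1, 80), st.floats(0.0, 10.0)),
                    min_size=0, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_lattice_oracle(self, raw):
        # snap to the lattice so edge effects cannot straddle a lattice cell
        bands = [B(round(lo, 1), round(lo + w, 1)) for lo, w in raw]
        per_task = {"grasp": bands[: len(bands) // 2], "open": bands[len(bands) // 2:]}
        merged = merge_bands(per_task)
        oracle = lattice_union(per_task)
        assert len(merged) == len(oracle)
        for b, (lo, hi) in zip(merged, oracle):
            assert b.lo_hz == pytest.approx(lo, abs=0.11)
            assert b.hi_hz == pytest.approx(hi, abs=0.11)


class TestExclusionRule:
    def test_no_bands_means_no_filter(self):
        assert exclusion_rule([]) is False

    def test_single_peak_only_band_means_no_filter(self):
        assert exclusion_rule([B(10, 10)]) is False

    def test_real_band_is_filter_eligible(self):
        assert exclusion_rule([B(8, 12)]) is True

    def test_min_width_applies(self):
        assert exclusion_rule([B(8, 8.5)], min_width_hz=1.0) is False
        assert exclusion_rule([B(8, 9.5)], min_width_hz=1.0) is True


def _gain_db(cascade, f):
    h = 1.0 + 0j
    for sos in cascade:
        _, resp = sg.sosfreqz(sos, worN=[2 * np.pi * f / FS])
        h *= resp[0]
    return 20 * np.log10(abs(h))


class TestDesignBandstop:
    def test_deep_notch_at_band_center(self):
        cascade = design_bandstop([B(8, 13)], FS)
        assert _gain_db(cascade, np.sqrt(8 * 13)) <= -20.0

    def test_unity_outside_band(self):
        cascade = design_bandstop([B(8, 13)], FS)
        assert abs(_gain_db(cascade, 35.0)) <= 1.0

    def test_empty_band_list_is_identity(self):
        assert design_bandstop([], FS) == []

    def test_band_touching_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            design_bandstop([B(400, 500.0)], FS)

    @given(lo=st.floats(3.0, 90.0), width=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_designed_filters_always_stable(self, lo, width):
        cascade = design_bandstop([B(lo, lo + width)], FS)
        for sos in cascade:
            _, poles, _ = sg.sos2zpk(sos)
            assert np.all(np.abs(poles) < 1.0)


def _tone_signal(f, dur=4.0, channels=("mDEL", "FCR")):
    t = np.arange(int(dur * FS)) / FS
    tone = np.sin(2 * np.pi * f * t)
    return TaskSignal(samples=np.vstack([tone] * len(channels)), fs=FS,
                      channels=channels, task="grasp", loading="sabd50")


class TestApplyFilterbank:
    def _bank(self):
        return FilterBank("S", "sabd50", FS, {"FCR": [B(8, 13)]})

    def test_stop_band_tone_suppressed_to_five_percent(self):
        sig = _tone_signal(10.0)
        out = apply_filterbank(sig, self._bank())
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert rms(out.channel("FCR")) <= 0.05 * rms(sig.channel("FCR"))

    def test_out_of_band_tone_preserved(self):
        sig = _tone_signal(30.0)
        out = apply_filterbank(sig, self._bank())
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert abs(rms(out.channel("FCR")) / rms(sig.channel("FCR")) - 1) <= 0.10

    def test_unlisted_channel_passes_through_bit_identical(self):
        sig = _tone_signal(10.0)
        out = apply_filterbank(sig, self._bank())
        np.testing.assert_array_equal(out.channel("mDEL"), sig.channel("mDEL"))

    def test_unknown_channel_rejected(self):
        sig = _tone_signal(10.0)
        bank = FilterBank("S", "sabd50", FS, {"EDC": [B(8, 13)]})
        with pytest.raises(ValueError, match="EDC"):
            apply_filterbank(sig, bank)

    def test_energy_outside_stop_bands_preserved(self, rng):
        """Broadband noise keeps >=90% of its power outside the stop band +/- 2 Hz."""
        x = rng.standard_normal(int(8 * FS))
        sig = TaskSignal(samples=np.vstack([x, x]), fs=FS, channels=("mDEL", "FCR"),
                         task="grasp", loading="sabd50")
        out = apply_filterbank(sig, self._bank())
        f, p_in = sg.welch(sig.channel("FCR"), fs=FS, nperseg=2048)
        _, p_out = sg.welch(out.channel("FCR"), fs=FS, nperseg=2048)
        guard = (f < 6.0) | (f > 15.0)
        ratio = p_out[guard].sum() / p_in[guard].sum()
        assert 0.90 <= ratio <= 1.05

    def test_roundtrip_serialisation(self, tmp_path):
        bank = FilterBank("S07", "sabd25", FS, {"FCR": [B(8, 13)], "FDS": []},
                          eligible=True)
        bank.to_json(tmp_path / "bank.json")
        back = FilterBank.from_json(tmp_path / "bank.json")
        assert back == bank
        assert back.applied_channels == ("FCR",)


class TestSteadyPhase:
    def test_margin_trims_each_repetition(self, rng):
        sig = TaskSignal(samples=rng.standard_normal((1, 3000)), fs=1000.0,
                         channels=("a",), task="grasp", loading="sabd50",
                         source_trials=[1, 2, 3], segment_lengths=[1000, 1000, 1000])
        out = steady_phase(sig, 0.25)
        assert out.segment_lengths == [500, 500, 500]
        np.testing.assert_array_equal(out.samples[:, :500], sig.samples[:, 250:750])


class TestBuildSubjectFilters:
    def test_separate_loadings_yield_independent_banks(self):
        profile = SubjectProfile(severity=1.0)
        proto = ProtocolSpec(loadings=("sabd25", "sabd50"), repetitions=3,
                             trial_duration_s=2.0, seed=5)
        rec = generate_session(profile, proto)
        cfg = SynergyFilterConfig(
            coherence=CoherenceConfig(n_surrogates=100, surrogate_duration_s=4.0))
        banks = build_subject_filters(rec, cfg, seed=5)
        assert set(banks) == {"sabd25", "sabd50"}
        for loading, bank in banks.items():
            assert bank.loading == loading
            assert set(bank.stop_bands) == {"FCR", "FDS", "ECR", "EDC"}

    def test_missing_task_rejected(self):
        profile = SubjectProfile()
        proto = ProtocolSpec(tasks=("open", "grasp"), loadings=("sabd50",),
                             repetitions=2, trial_duration_s=2.0, seed=1)
        rec = generate_session(profile, proto)
        with pytest.raises(ValueError, match="relax"):
            build_subject_filters(rec, SynergyFilterConfig(), seed=1)
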