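"""Trace rendering and cohort generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melt2d import genotypes as gt
from melt2d.panel import Allele, Channel, Ploidy
from melt2d.simulate import (
    FIXTURE_ALLELE_FREQUENCIES,
    DuplexComponent,
    SampleGenotype,
    SimulationParams,
    components_for_sample,
    default_grid,
    fixture_cohort,
    render_channel,
    sample_cohort,
    simulate_sample,
)


def all_wild(panel):
    return {l.locus_id: gt.WILD_CLASS[l.ploidy] for l in panel.loci}


def all_mutant(panel):
    return {
        l.locus_id: gt.MM if l.ploidy == Ploidy.DIPLOID else gt.MUTANT_HOMOPLASMIC
        for l in panel.loci
    }


class TestRenderChannel:
    def test_single_component_derivative_peaks_at_tm(self):
        trace = render_channel([DuplexComponent(tm_c=64.4, amplitude=1.0, width_c=0.5)])
        t, f = trace.temperatures, trace.fluorescence
        neg = -np.gradient(f, t)
        assert abs(t[np.argmax(neg)] - 64.4) <= 0.1 + 1e-9

    def test_empty_components_flat_zero(self):
        trace = render_channel([])
        assert np.allclose(trace.fluorescence, 0.0)

    def test_two_components_resolvable(self):
        comps = [DuplexComponent(66.8, 1.0, 0.5), DuplexComponent(64.4, 1.0, 0.5)]
        trace = render_channel(comps)
        neg = -np.gradient(trace.fluorescence, trace.temperatures)
        # local maxima of the exact derivative near each Tm
        peaks = [
            trace.temperatures[i]
            for i in range(1, len(neg) - 1)
            if neg[i] > neg[i - 1] and neg[i] > neg[i + 1] and neg[i] > 0.1
        ]
        assert len(peaks) == 2
        assert min(abs(p - 66.8) for p in peaks) <= 0.1
        assert min(abs(p - 64.4) for p in peaks) <= 0.1

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            render_channel([], grid=np.array([30.0, 30.0, 31.0]))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            render_channel([], noise_sd=-1.0)

    def test_default_grid_spans_ramp(self):
        g = default_grid()
        assert g[0] == 30.0 and g[-1] == 70.0 and len(g) == 401


class TestSimulateSample:
    def test_all_wild_leaves_alexa_empty(self, panel):
        comps = components_for_sample(panel, SampleGenotype("s", all_wild(panel)))
        assert comps[Channel.ALEXA568] == []
        fam_tms = sorted(c.tm_c for c in comps[Channel.FAM])
        assert fam_tms == [36.4, 41.2, 48.4, 53.2, 59.6, 64.4, 66.8]
        hex_tms = sorted(c.tm_c for c in comps[Channel.HEX])
        assert hex_tms == [42.4, 47.2]

    def test_all_mutant_leaves_fam_empty(self, panel):
        comps = components_for_sample(panel, SampleGenotype("s", all_mutant(panel)))
        assert comps[Channel.FAM] == []
        assert sorted(c.tm_c for c in comps[Channel.HEX]) == [56.4, 59.6, 63.2, 67.2]
        assert sorted(c.tm_c for c in comps[Channel.ALEXA568]) == [35.6, 41.6, 50.4, 62.0, 66.0]

    def test_heterozygote_half_amplitude(self, panel):
        calls = all_wild(panel)
        calls["c.235delC"] = gt.WM
        comps = components_for_sample(panel, SampleGenotype("s", calls))
        fam = {c.tm_c: c.amplitude for c in comps[Channel.FAM]}
        hexc = {c.tm_c: c.amplitude for c in comps[Channel.HEX]}
        assert fam[64.4] == 0.5
        assert hexc[63.2] == 0.5
        assert fam[66.8] == 1.0  # other loci unaffected

    def test_component_count_matches_present_alleles(self, panel):
        rng = np.random.default_rng(3)
        for _ in range(20):
            calls = {}
            for locus in panel.loci:
                calls[locus.locus_id] = rng.choice(gt.classes_for(locus.ploidy))
            sg = SampleGenotype("s", calls)
            comps = components_for_sample(panel, sg)
            for channel in Channel:
                expected = sum(
                    1
                    for locus in panel.loci
                    for allele in gt.allele_dosage(calls[locus.locus_id])
                    if panel.coordinate(locus.locus_id, allele).channel == channel
                )
                assert len(comps[channel]) == expected

    def test_missing_locus_rejected(self, panel):
        calls = all_wild(panel)
        del calls["c.235delC"]
        with pytest.raises(ValueError, match="missing loci"):
            simulate_sample(panel, SampleGenotype("s", calls))

    def test_seeded_reproducibility(self, panel):
        sg = SampleGenotype("s", all_wild(panel))
        a = simulate_sample(panel, sg, seed=11)
        b = simulate_sample(panel, sg, seed=11)
        for ch in Channel:
            np.testing.assert_array_equal(a[ch].fluorescence, b[ch].fluorescence)


class TestFixtureCohort:
    def test_size_and_carriers(self, panel, fixture116):
        assert len(fixture116) == 116
        carriers = sum(
            any(c in gt.MUTANT_BEARING for c in s.calls.values()) for s in fixture116
        )
        assert carriers == 50
        all_wild_n = sum(
            all(c not in gt.MUTANT_BEARING for c in s.calls.values()) for s in fixture116
        )
        assert all_wild_n == 66

    def test_triple_mutation_sample_exists(self, fixture116):
        """One patient carries the SLC26A4 compound het plus homoplasmic m.1555A>G."""
        triples = [
            s
            for s in fixture116
            if s.calls["c.919-2A>G"] == gt.WM
            and s.calls["c.2168A>G"] == gt.WM
            and s.calls["m.1555A>G"] == gt.MUTANT_HOMOPLASMIC
        ]
        assert len(triples) == 1


class TestSampleCohort:
    def test_degenerate_frequencies(self, panel):
        cohort = sample_cohort(panel, 20, {l: 0.0 for l in panel.locus_ids}, seed=1)
        assert all(
            c not in gt.MUTANT_BEARING for s in cohort for c in s.calls.values()
        )
        cohort = sample_cohort(panel, 20, {"c.235delC": 1.0}, seed=1)
        assert all(s.calls["c.235delC"] == gt.MM for s in cohort)

    def test_frequency_recovery_large_n(self, panel):
        f = FIXTURE_ALLELE_FREQUENCIES["c.235delC"]  # 0.1595
        n = 10_000
        cohort = sample_cohort(panel, n, {"c.235delC": f}, seed=5)
        alleles = sum(
            {"WW": 0, "WM": 1, "MM": 2}[s.calls["c.235delC"]] for s in cohort
        )
        observed = alleles / (2 * n)
        se = np.sqrt(f * (1 - f) / (2 * n))
        assert abs(observed - f) < 3 * se

    def test_invalid_frequency_rejected(self, panel):
        with pytest.raises(ValueError, match="outside"):
            sample_cohort(panel, 5, {"c.235delC": 1.5}, seed=0)
        with pytest.raises(ValueError, match="unknown locus"):
            sample_cohort(panel, 5, {"c.9999A>G": 0.1}, seed=0)

    def test_seeded_determinism(self, panel):
        a = sample_cohort(panel, 50, FIXTURE_ALLELE_FREQUENCIES, seed=9)
        b = sample_cohort(panel, 50, FIXTURE_ALLELE_FREQUENCIES, seed=9)
        assert [s.calls for s in a] == [s.calls for s in b]


@settings(max_examples=25, deadline=None)
@given(st.floats(min_value=35.0, max_value=65.0), st.floats(min_value=0.3, max_value=1.0))
def test_isolated_component_peak_position(tm, width):
    """The exact negative derivative of one sigmoid peaks at its Tm."""
    trace = render_channel([DuplexComponent(tm_c=tm, amplitude=1.0, width_c=width)])
    neg = -np.gradient(trace.fluorescence, trace.temperatures)
    assert abs(trace.temperatures[np.argmax(neg)] - tm) <= 0.1 + 1e-9
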