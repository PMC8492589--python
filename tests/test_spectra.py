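"""Peak-list I/O, precursor matching, artifact flagging, abundance ranking."""

import pytest

from scmetox.rules import enumerate_candidates
from scmetox.simulate import simulate_incubations, study_incubation_config
from scmetox.spectra import (
    PeakListError,
    SpectrumRecord,
    flag_artifacts,
    match_candidates,
    rank_abundance,
    read_peaklists,
    write_peaklists,
)


def _record(analyte="m1", incubation="pHLM", mz=385.1911, intensity=1e6,
            rt=5.0, fragments=((155.0491, 100.0), (114.0913, 60.0))):
    return SpectrumRecord(analyte, incubation, mz, rt, intensity, list(fragments))


class TestRecordValidation:
    def test_rejects_nonpositive_precursor(self):
        with pytest.raises(ValueError):
            _record(mz=0.0)

    def test_rejects_out_of_range_fragment_intensity(self):
        with pytest.raises(ValueError):
            _record(fragments=[(100.0, 150.0)])

    def test_relative_rescaling_sets_base_peak_to_100(self):
        rec = SpectrumRecord.with_relative_fragments(
            "m", "pHLM", 200.0, [100.0, 120.0], [5e4, 2e5]
        )
        assert max(i for _, i in rec.fragments) == pytest.approx(100.0)


class TestIO:
    @pytest.mark.parametrize("ext", ["mgf", "csv"])
    def test_round_trip_lossless_at_four_decimals(self, tmp_path, ext):
        spectra = simulate_incubations(study_incubation_config("JWH-200", seed=1))
        records = spectra["pHLM"]
        path = tmp_path / f"phlm.{ext}"
        write_peaklists(records, str(path))
        back = read_peaklists(str(path))
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert (a.analyte_id, a.incubation) == (b.analyte_id, b.incubation)
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=5e-5)
            assert b.rt_min == pytest.approx(a.rt_min, abs=1e-3)
            for (m1, i1), (m2, i2) in zip(a.fragments, b.fragments):
                assert m2 == pytest.approx(m1, abs=5e-5)
                assert i2 == pytest.approx(i1, abs=5e-3)

    def test_single_mgf_block_parses_to_one_record(self, tmp_path):
        path = tmp_path / "one.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=analyte=m1 incubation=pHLM\n"
            "PEPMASS=385.1911 1000000\nRTINSECONDS=300\n"
            "155.0491 100\n114.0913 60\n145.0647 20\n70.0651 10\nEND IONS\n"
        )
        records = read_peaklists(str(path))
        assert len(records) == 1
        assert records[0].analyte_id == "m1"
        assert len(records[0].fragments) == 4

    def test_truncated_mgf_reports_location(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text("BEGIN IONS\nPEPMASS=385.19\n155.05 10\n")
        with pytest.raises(PeakListError, match="line 1"):
            read_peaklists(str(path))

    def test_csv_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("analyte_id,precursor_mz\nm1,385.19\n")
        with pytest.raises(PeakListError, match="incubation"):
            read_peaklists(str(path))

    def test_empty_csv_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "analyte_id,incubation,precursor_mz,rt_min,precursor_intensity,"
            "fragment_mz_list,fragment_intensity_list\n"
        )
        assert read_peaklists(str(path)) == []


class TestMatching:
    def test_ester_hydrolysis_precursor_matches(self, emb_pinaca):
        cands = enumerate_candidates(emb_pinaca, max_depth=1)
        matches = match_candidates([_record(mz=350.1874)], cands, tol_mda=5.0)
        assert any(m.candidate_id.endswith("ester_hydrolysis") for m in matches)

    def test_parent_does_not_match_distant_precursor(self, emb_pinaca):
        parent_only = enumerate_candidates(emb_pinaca, max_depth=0)
        assert match_candidates([_record(mz=350.1874)], parent_only, tol_mda=5.0) == []

    def test_empty_spectra_give_empty_matches(self, emb_pinaca):
        cands = enumerate_candidates(emb_pinaca, max_depth=1)
        assert match_candidates([], cands) == []

    def test_matches_ranked_by_error_then_depth(self, jwh200):
        cands = enumerate_candidates(jwh200, max_depth=2)
        matches = match_candidates([_record(mz=401.1859)], cands, tol_mda=5.0)
        assert len(matches) >= 1
        errors = [abs(m.error_mda) for m in matches]
        assert errors == sorted(errors)

    def test_rejects_nonpositive_tolerance(self, jwh200):
        with pytest.raises(ValueError):
            match_candidates(
                [], enumerate_candidates(jwh200, max_depth=0), tol_mda=0.0
            )

    def test_recovers_all_planted_metabolites_at_small_mass_error(self, emb_pinaca):
        # mass error sd 0.5 mDa << 5 mDa tolerance: identification of the
        # planted truth must be perfect (precision and recall 1.0)
        config = study_incubation_config("5F-EMB-PINACA", seed=11)
        spectra = simulate_incubations(config)["pHLM"]
        cands = enumerate_candidates(emb_pinaca, max_depth=2)
        matches = match_candidates(spectra, cands, tol_mda=5.0)
        best = {}
        for m in matches:  # already ranked per spectrum; keep the top hit
            best.setdefault(m.spectrum_id, m)
        planted = {
            f"5F-EMB-PINACA|{'+'.join(sorted(met.rules))}"
            for met in config.metabolites
        }
        recovered = {m.candidate_id for m in best.values()}
        assert planted <= recovered  # recall 1.0
        for m in best.values():  # precision 1.0: top hit is the true analyte
            assert m.candidate_id == m.analyte_id.split("#")[0]


class TestArtifactFlagging:
    def test_control_peak_at_similar_intensity_is_flagged(self):
        treated = [_record(analyte="hydroxy", intensity=1e6)]
        control = [_record(analyte="hydroxy", incubation="negative control",
                           intensity=1.1e6)]
        assert flag_artifacts(treated, control) == {"hydroxy"}

    def test_peak_absent_from_control_is_not_flagged(self):
        assert flag_artifacts([_record()], []) == set()

    def test_trace_level_control_peak_is_not_flagged(self):
        treated = [_record(analyte="met", intensity=1e6)]
        control = [_record(analyte="met", incubation="negative control",
                           intensity=1e4)]
        assert flag_artifacts(treated, control) == set()

    def test_invariant_under_common_intensity_rescaling(self):
        treated = [_record(analyte="a", intensity=2e5),
                   _record(analyte="b", mz=401.186, intensity=8e5)]
        control = [_record(analyte="a", incubation="negative control",
                           intensity=3e5)]
        base = flag_artifacts(treated, control)
        scale = 37.5
        treated2 = [_record(analyte=r.analyte_id, mz=r.precursor_mz,
                            intensity=r.precursor_intensity * scale)
                    for r in treated]
        control2 = [_record(analyte=r.analyte_id, incubation=r.incubation,
                            mz=r.precursor_mz,
                            intensity=r.precursor_intensity * scale)
                    for r in control]
        assert flag_artifacts(treated2, control2) == base

    def test_rt_gate_separates_isobaric_isomers(self):
        treated = [_record(analyte="true_met", rt=3.0, intensity=1e6)]
        control = [_record(analyte="artifact", incubation="negative control",
                           rt=9.0, intensity=1e6)]
        assert flag_artifacts(treated, control) == {"true_met"}
        assert flag_artifacts(treated, control, rt_tol_min=0.5) == set()


class TestAbundanceRanking:
    def _set(self):
        spectra = [
            _record(analyte="m1", mz=300.1, intensity=5e5),
            _record(analyte="m2", mz=310.1, intensity=9e5),
            _record(analyte="m3", mz=320.1, intensity=1e5),
            _record(analyte="m4", mz=305.1, intensity=9e5),  # tie with m2
        ]
        matches = [
            type("M", (), {"analyte_id": r.analyte_id})() for r in spectra
        ]
        return matches, spectra

    def test_descending_intensity_with_mz_tie_break(self):
        matches, spectra = self._set()
        # tie between m2 (310.1) and m4 (305.1): lower m/z first
        assert rank_abundance(matches, spectra, 4) == ["m4", "m2", "m1", "m3"]

    def test_top_n_truncates(self):
        matches, spectra = self._set()
        assert rank_abundance(matches, spectra, 2) == ["m4", "m2"]

    def test_top_n_larger_than_count_returns_all(self):
        matches, spectra = self._set()
        assert len(rank_abundance(matches, spectra, 99)) == 4
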