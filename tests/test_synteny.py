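"""CDS coordinate parsing, 11-gene windows and neighbor conservation."""

import pytest

from pansynteny.proteome import read_annotation_tsv
from pansynteny.simulate import round_half_up
from pansynteny.synteny import (
    GeneLocus,
    annotate_windows,
    build_windows,
    neighbor_conservation,
    parse_cds_coordinates,
    select_syntenic_clusters,
)


def _locus(pid: str, start: int, genome="g", end=None) -> GeneLocus:
    return GeneLocus(
        genome_id=genome, chromosome_id=genome, protein_id=pid,
        start=start, end=end if end is not None else start + 99, strand="+",
    )


def _chromosome(n: int, genome="g") -> list[GeneLocus]:
    return [_locus(f"p{i:02d}", 1 + 200 * i, genome=genome) for i in range(n)]


class TestParseCoordinates:
    def _write(self, tmp_path, headers):
        p = tmp_path / "g_cds.fna"
        p.write_text("".join(f">{h}\nATG\n" for h in headers))
        return p

    def test_location_grammar(self, tmp_path):
        p = self._write(tmp_path, [
            "lcl|c1 [protein_id=A] [location=10..90]",
            "lcl|c2 [protein_id=B] [location=complement(1234..5678)]",
            "lcl|c3 [protein_id=C] [location=join(10..50,400..500)]",
        ])
        loci = {l.protein_id: l for l in parse_cds_coordinates(p)}
        assert (loci["A"].start, loci["A"].end, loci["A"].strand) == (10, 90, "+")
        assert (loci["B"].start, loci["B"].end, loci["B"].strand) == (1234, 5678, "-")
        assert (loci["C"].start, loci["C"].end) == (10, 500)
        assert loci["C"].compound and not loci["A"].compound

    def test_unusable_headers_skipped_with_warning(self, tmp_path, caplog):
        p = self._write(tmp_path, [
            "lcl|c1 [protein_id=A] [location=10..90]",
            "lcl|c2 [location=5..9]",            # no protein_id
            "lcl|c3 [protein_id=C]",             # no location
            "lcl|c4 [protein_id=D] [location=??]",  # unparseable
        ])
        with caplog.at_level("WARNING"):
            loci = parse_cds_coordinates(p)
        assert [l.protein_id for l in loci] == ["A"]
        assert "skipped 3" in caplog.text


class TestBuildWindows:
    def test_interior_gene_gets_eleven(self):
        loci = _chromosome(20)
        windows, missing = build_windows(loci, {"p10"})
        assert not missing
        assert len(windows) == 1 and len(windows[0]) == 11

    def test_first_gene_truncates_to_six(self):
        windows, _ = build_windows(_chromosome(20), {"p00"})
        assert len(windows[0]) == 6

    def test_short_chromosome_center_at_ordinal_four(self):
        windows, _ = build_windows(_chromosome(8), {"p03"})
        assert len(windows[0]) == 8  # 3 upstream + center + 4 downstream

    def test_duplicated_center_yields_window_per_occurrence(self):
        loci = _chromosome(20)
        loci[15] = _locus("p03", loci[15].start)  # second copy of p03
        windows, _ = build_windows(loci, {"p03"})
        assert len(windows) == 2

    def test_missing_center_reported(self):
        windows, missing = build_windows(_chromosome(5), {"p01", "absent"})
        assert missing == {"absent"}
        assert len(windows) == 1

    def test_neighbors_ordered_and_exclude_center(self):
        windows, _ = build_windows(_chromosome(20), {"p10"})
        w = windows[0]
        ids = [n.protein_id for n in w.neighbors]
        assert "p10" not in ids
        assert ids == sorted(ids)


class TestAnnotateAndConserve:
    def _annotated_windows(self, adjacency: dict[str, bool]):
        """One window per genome; KO K00001 adjacent iff adjacency[genome]."""
        windows = []
        for gid, has_ko in adjacency.items():
            loci = _chromosome(11, genome=gid)
            ws, _ = build_windows(loci, {"p05"})
            ann = {"p04": "K00001"} if has_ko else {}
            annotate_windows(ws, ann)
            windows.extend(ws)
        return windows

    def test_blanks_exactly_at_unmapped_ids(self):
        ws, _ = build_windows(_chromosome(11), {"p05"})
        annotate_windows(ws, {"p04": "K00001", "p06": "K00002"})
        kos = dict(zip((n.protein_id for n in ws[0].neighbors), ws[0].neighbor_kos))
        assert kos["p04"] == "K00001" and kos["p06"] == "K00002"
        assert all(v == "" for k, v in kos.items() if k not in ("p04", "p06"))

    def test_three_of_four_genomes_is_not_conserved(self):
        windows = self._annotated_windows(
            {"g1": True, "g2": True, "g3": True, "g4": False}
        )
        rec = neighbor_conservation(0, windows, cutoff=0.75)
        assert rec.ko_fraction["K00001"] == pytest.approx(0.75)
        assert "K00001" not in rec.conserved_kos

    def test_all_genomes_conserved(self):
        windows = self._annotated_windows({f"g{i}": True for i in range(4)})
        rec = neighbor_conservation(0, windows, cutoff=0.75)
        assert rec.ko_fraction["K00001"] == 1.0
        assert rec.conserved_kos == ["K00001"]

    def test_never_adjacent_ko_absent(self):
        windows = self._annotated_windows({"g1": False, "g2": False})
        rec = neighbor_conservation(0, windows)
        assert "K00001" not in rec.ko_fraction

    def test_duplicate_windows_count_genome_once(self):
        loci = _chromosome(20, genome="g1")
        loci[15] = _locus("p05", loci[15].start, genome="g1")
        ws, _ = build_windows(loci, {"p05"})
        annotate_windows(ws, {"p04": "K00001"})
        rec = neighbor_conservation(0, ws)
        assert rec.ko_fraction["K00001"] == 1.0  # one genome, counted once

    def test_no_windows_rejected(self):
        with pytest.raises(ValueError):
            neighbor_conservation(0, [])


class TestSelection:
    def test_retains_only_clusters_with_conserved_ko(self):
        windows_yes = TestAnnotateAndConserve()._annotated_windows(
            {f"g{i}": True for i in range(4)}
        )
        windows_no = TestAnnotateAndConserve()._annotated_windows(
            {"g1": True, "g2": False, "g3": False, "g4": False}
        )
        recs = [
            neighbor_conservation(1, windows_yes),
            neighbor_conservation(2, windows_no),
        ]
        assert select_syntenic_clusters(recs) == {1: ["K00001"]}


class TestPlantedNeighborhoods:
    def test_planted_ko_fraction_matches_manifest_exactly(self, small_sim):
        d, cfg, truth = small_sim
        ann = read_annotation_tsv(d / "annotations.tsv")
        loci = []
        for gid in truth.genome_ids:
            loci.extend(parse_cds_coordinates(d / f"{gid}_cds.fna", genome_id=gid))
        for fam in truth.families:
            members = set(fam["members"].values())
            windows, missing = build_windows(loci, members)
            assert not missing
            annotate_windows(windows, ann)
            rec = neighbor_conservation(0, windows, cutoff=0.75)
            n_carriers = len(fam["carrier_genomes"])
            assert rec.n_genomes_with_windows == n_carriers
            expected = len(fam["preserved_genomes"]) / n_carriers
            for ko in fam["planted_kos"]:
                assert rec.ko_fraction.get(ko, 0.0) == pytest.approx(expected)

    def test_high_preservation_selected_low_preservation_excluded(self, small_sim):
        d, cfg, truth = small_sim
        ann = read_annotation_tsv(d / "annotations.tsv")
        loci = []
        for gid in truth.genome_ids:
            loci.extend(parse_cds_coordinates(d / f"{gid}_cds.fna", genome_id=gid))
        recs = []
        for i, fam in enumerate(truth.families):
            windows, _ = build_windows(loci, set(fam["members"].values()))
            annotate_windows(windows, ann)
            recs.append(neighbor_conservation(i, windows, cutoff=0.75))
        selected = select_syntenic_clusters(recs)
        preservation = cfg.neighbor_preservation_list()
        for i, fam in enumerate(truth.families):
            if preservation[i] > 0.75:
                assert i in selected
                assert set(fam["planted_kos"]) <= set(selected[i])
            else:
                assert i not in selected
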