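"""Plot-spec computation: layout, orientation, labels, panels, rendering."""

import json

import numpy as np
import pytest

import gwasviz as gv
from gwasviz.errors import MissingColumnError, ValidationError
from gwasviz.plots import pack_gene_rows, r2_bin
from gwasviz.plotspec import broadcast_option, repel_labels, Label
from gwasviz.regions import Region

from conftest import make_dataset


class TestGenomeLayout:
    def test_single_chromosome_degenerate(self):
        d = make_dataset([("1", 10, 0.1), ("1", 100, 0.2)])
        lay = gv.genome_layout([d])
        assert lay.offsets == {"1": 0.0}
        assert lay.ticks().ticks == [50.0]
        assert lay.shades() == []  # shading alternates from the second chromosome

    def test_two_chromosome_offset_arithmetic(self):
        d = make_dataset([("1", 100, 0.1), ("2", 50, 0.2)])
        lay = gv.genome_layout([d])
        assert lay.offsets["1"] == 0.0
        assert lay.offsets["2"] == pytest.approx(100 + lay.gap)
        assert lay.gap == pytest.approx(0.003 * 150)

    def test_layout_depends_only_on_coordinates(self):
        d1 = make_dataset([("1", 100, 0.1), ("2", 50, 0.2)], label="a")
        d2 = make_dataset([("1", 100, 0.9), ("2", 50, 0.9)], label="b")
        l1 = gv.genome_layout([d1])
        l2 = gv.genome_layout([d1, d2])
        assert l1.offsets == l2.offsets

    def test_x_strictly_increases_within_chromosome(self, sim_data):
        lay = gv.genome_layout([sim_data])
        for chrom, grp in sim_data.df.groupby("CHROM"):
            x = lay.x(chrom, np.sort(grp["POS"].unique()))
            assert (np.diff(x) > 0).all()

    def test_tick_labels_in_canonical_order(self, sim_data):
        ax = gv.genome_layout([sim_data]).ticks()
        assert ax.tick_labels == ["1", "2", "3", "X"]


class TestSplitNtop:
    @pytest.mark.parametrize(
        "n, ntop, expected",
        [
            (2, 1, ["top", "bottom"]),
            (3, 3, ["top", "top", "top"]),
            (2, 0, ["bottom", "bottom"]),
            (3, None, ["top", "top", "top"]),
        ],
    )
    def test_assignment(self, n, ntop, expected):
        assert gv.split_ntop(n, ntop) == expected

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            gv.split_ntop(2, 3)
        with pytest.raises(ValidationError):
            gv.split_ntop(2, -1)


class TestSelectLabels:
    def test_per_dataset_thresholds_match_direct_lead_calls(self):
        rng = np.random.default_rng(2)
        ds = [
            make_dataset(
                {
                    "CHROM": ["1"] * 200,
                    "POS": rng.integers(1, 5_000_000, 200),
                    "P": 10.0 ** (-rng.uniform(0, 14, 200)),
                },
                label=f"d{i}",
            )
            for i in range(2)
        ]
        labels = gv.select_labels(ds, annotate=[1e-12, 1e-8], region_size=500_000)
        for d, th, got in zip(ds, [1e-12, 1e-8], labels):
            exp = gv.get_lead_snps(d, thresh=th, region_size=500_000)
            assert list(got["POS"]) == list(exp["POS"])

    def test_gene_column_used_verbatim(self):
        d = make_dataset([("1", 100, 1e-10)], GENE=["MYGENE"])
        labels = gv.select_labels([d], annotate=1e-8, track=None)[0]
        assert list(labels["text"]) == ["MYGENE"]

    def test_no_annotate_no_labels(self, sim_data):
        assert len(gv.select_labels([sim_data], annotate=None)[0]) == 0

    def test_vector_length_mismatch(self, sim_data):
        with pytest.raises(ValidationError):
            gv.select_labels([sim_data], annotate=[1e-8, 1e-9])


class TestManhattan:
    def test_default_spec_anatomy(self, sim_data):
        spec = gv.manhattan(sim_data)
        main = spec.panel("main")
        assert len(main.points) == 1
        assert len(main.hlines) == 1
        assert main.hlines[0].y == pytest.approx(-np.log10(5e-8))
        assert main.labels == []
        assert spec.legend is None

    def test_sign_thresh_removable_and_multiple(self, sim_data):
        assert gv.manhattan(sim_data, sign_thresh=None).panel("main").hlines == []
        ys = sorted(
            h.y for h in gv.manhattan(sim_data, sign_thresh=[5e-8, 1e-6]).panel("main").hlines
        )
        assert ys == pytest.approx(sorted([-np.log10(5e-8), -np.log10(1e-6)]))

    def test_three_overlapping_datasets_with_legend(self, sim_data):
        ds = [sim_data.subset(sim_data.df["P"] < 1, label=f"d{i}") for i in range(3)]
        spec = gv.manhattan(ds, ntop=3)
        assert [p.orientation for p in spec.panel("main").points] == ["top"] * 3
        assert len(spec.legend.entries) == 3

    def test_mirrored_orientation_sign_convention(self, sim_data):
        ds = [sim_data.subset(sim_data.df["P"] < 1, label=f"d{i}") for i in range(2)]
        spec = gv.manhattan(ds, ntop=1)
        top, bottom = spec.panel("main").points
        assert min(top.y, default=0) >= 0
        assert max(bottom.y, default=0) <= 0
        # mirrored threshold line drawn on both halves
        assert sorted(h.y for h in spec.panel("main").hlines) == pytest.approx(
            [np.log10(5e-8), -np.log10(5e-8)]
        )

    def test_highlight_genes_markers(self, sim_data, sim_track):
        names = [sim_track.genes[0].gene_name, sim_track.genes[1].gene_name]
        spec = gv.manhattan(sim_data, highlight_genes=names, track=sim_track)
        strip = spec.panel("genes")
        lay = gv.genome_layout([sim_data])
        assert sorted(g.name for g in strip.genes) == sorted(names)
        for g in strip.genes:
            model = sim_track.by_name(g.name)
            assert g.start == pytest.approx(lay.x(model.chrom, model.gene_start))

    def test_labels_match_lead_selection(self, sim_data, sim_track):
        spec = gv.manhattan(sim_data, annotate=1e-9, track=sim_track)
        leads = gv.get_lead_snps(sim_data, thresh=1e-9)
        assert len(spec.panel("main").labels) == len(leads)

    def test_style_vector_mismatch_rejected(self, sim_data):
        with pytest.raises(ValidationError):
            gv.manhattan([sim_data], color=["red", "blue"])

    def test_annotate_with_vline_adds_vlines(self, sim_data, sim_track):
        spec = gv.manhattan(sim_data, annotate=1e-9, annotate_with_vline=True, track=sim_track)
        main = spec.panel("main")
        assert len(main.vlines) == len(main.labels) > 0

    def test_spec_serialises_to_json(self, sim_data, sim_track):
        spec = gv.manhattan(sim_data, annotate=1e-9, track=sim_track)
        round_tripped = json.loads(spec.to_json())
        assert round_tripped == spec.to_dict()

    def test_spec_deterministic(self, sim_data, sim_track):
        a = gv.manhattan(sim_data, annotate=1e-9, track=sim_track).to_dict()
        b = gv.manhattan(sim_data, annotate=1e-9, track=sim_track).to_dict()
        assert a == b


class TestRegionplot:
    def test_three_panels_and_region_text(self, sim_data, sim_track):
        spec = gv.regionplot(sim_data, region="1:1000000-2000000", track=sim_track)
        assert [p.kind for p in spec.panels] == ["overview", "main", "genes"]
        assert spec.region_text == "1:1000000-2000000"
        assert spec.panel("main").x_range == (1_000_000.0, 2_000_000.0)

    def test_gene_spec_padding_propagates(self, sim_data, sim_track):
        g = sim_track.genes[0]
        spec = gv.regionplot(sim_data, gene=g.gene_name, track=sim_track)
        lo = max(1, g.gene_start - 100_000)
        assert spec.panel("main").x_range == (float(lo), float(g.gene_end + 100_000))
        rect = spec.panel("overview").rects[0]
        assert rect.x0 <= lo and rect.x1 >= g.gene_end + 100_000

    def test_exon_rule_boundary(self, sim_data, sim_track):
        below = gv.regionplot(sim_data, region="1:1000000-1900000", track=sim_track)
        above = gv.regionplot(sim_data, region="1:1000000-2100000", track=sim_track)
        assert all(g.show_exons for g in below.panel("genes").genes)
        assert not any(g.show_exons for g in above.panel("genes").genes)

    def test_show_exons_override(self, sim_data, sim_track):
        forced = gv.regionplot(
            sim_data, region="1:1000000-2100000", track=sim_track, show_exons=True
        )
        assert all(g.show_exons for g in forced.panel("genes").genes)

    def test_tiny_region_rect_has_minimum_width(self, sim_data, sim_track):
        spec = gv.regionplot(sim_data, region="1:1000000-1000100", track=sim_track)
        rect = spec.panel("overview").rects[0]
        chrom_span = spec.panel("overview").x_range[1]
        assert rect.x1 - rect.x0 >= 0.005 * chrom_span

    def test_main_points_confined_to_region(self, sim_data, sim_track):
        spec = gv.regionplot(sim_data, region="1:1000000-2000000", track=sim_track)
        for series in spec.panel("main").points:
            assert all(1_000_000 <= x <= 2_000_000 for x in series.x)


class TestGeneRows:
    def test_no_overlap_within_rows_on_dense_tracks(self):
        rng = np.random.default_rng(4)
        region = Region("1", 1, 1_000_000)
        for _ in range(20):
            genes = [
                gv.GeneModel(
                    f"G{i}",
                    "1",
                    int(s),
                    int(s) + int(rng.integers(1_000, 150_000)),
                )
                for i, s in enumerate(rng.integers(1, 900_000, size=rng.integers(2, 25)))
            ]
            glyphs = pack_gene_rows(genes, region, show_exons=False)
            rows = {}
            for g in glyphs:
                label_w = (len(g.name) + 1) * 0.012 * region.width
                rows.setdefault(g.row, []).append((g.start, max(g.end, g.start + label_w)))
            for spans in rows.values():
                spans.sort()
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    assert s2 > e1

    def test_exons_included_only_when_requested(self, tiny_track):
        region = Region("1", 1, 700_000)
        with_exons = pack_gene_rows(tiny_track.genes[:3], region, show_exons=True)
        without = pack_gene_rows(tiny_track.genes[:3], region, show_exons=False)
        assert any(g.exons for g in with_exons)
        assert not any(g.exons for g in without)


class TestLocuszoom:
    def _with_r2(self, sim_data, values=None):
        df = sim_data.df.copy()
        rng = np.random.default_rng(0)
        df["R2"] = rng.uniform(0, 1, len(df)) if values is None else values
        return gv.GwasDataset(df=df, label="lz")

    def test_missing_r2_rejected(self, sim_data):
        with pytest.raises(MissingColumnError):
            gv.locuszoom(sim_data, region="1:1-2000000")

    def test_all_zero_r2_single_bin(self, sim_data):
        d = self._with_r2(sim_data, values=0.0)
        spec = gv.locuszoom(d, region="1:1-2000000")
        assert [p.dataset for p in spec.panel("main").points] == ["0.0-0.2"]

    def test_bin_assignment(self):
        assert list(r2_bin([0.1, 0.3, 0.9])) == [0, 1, 4]
        assert list(r2_bin([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])) == [0, 1, 2, 3, 4, 4]

    def test_index_variant_distinct(self, sim_data):
        df = sim_data.df.copy()
        df["R2"] = 0.1
        df.loc[df.index[0], "R2"] = 1.0
        d = gv.GwasDataset(df=df, label="lz")
        spec = gv.locuszoom(d, region=("1", 1, 10_000_000))
        names = [p.dataset for p in spec.panel("main").points]
        assert "index variant" in names


class TestEffectplot:
    def test_self_comparison_on_identity_line(self, sim_data):
        spec = gv.effectplot(sim_data, sim_data.subset(sim_data.df["P"] < 1, label="b"))
        pts = spec.panels[0].points
        xs = sum([p.x for p in pts], [])
        ys = sum([p.y for p in pts], [])
        assert xs == pytest.approx(ys)
        assert any(a.slope == 1.0 for a in spec.panels[0].alines)

    def test_fill_and_label_colour_follow_p2(self, sim_data):
        snp = gv.get_snpset(sim_data, sim_data.subset(sim_data.df["P"] < 1, label="b"))
        snp.loc[snp.index[0], "P2"] = 0.01  # one non-replicating variant
        spec = gv.effectplot(snpset=snp)
        filled = {p.dataset: p for p in spec.panels[0].points}
        sig = [p for p in spec.panels[0].points if p.filled]
        non = [p for p in spec.panels[0].points if not p.filled]
        assert len(sig) == 1 and len(non) == 1
        assert len(non[0].x) == 1
        grey = [l for l in spec.panels[0].labels if l.color != "black"]
        assert len(grey) == 1

    def test_empty_snpset_axes_only(self, sim_data):
        snp = gv.get_snpset(sim_data, sim_data.subset(sim_data.df["P"] < 1, label="b")).iloc[0:0]
        spec = gv.effectplot(snpset=snp)
        assert sum(len(p.x) for p in spec.panels[0].points) == 0
        assert spec.panels[0].hlines and spec.panels[0].vlines


class TestRenderer:
    @pytest.mark.parametrize("ext", ["png", "svg", "pdf"])
    def test_figure_files_written(self, tmp_path, sim_data, sim_track, ext):
        spec = gv.manhattan(sim_data, annotate=1e-9, track=sim_track)
        out = tmp_path / f"fig.{ext}"
        gv.render(spec, str(out))
        assert out.exists() and out.stat().st_size > 0

    def test_regionplot_renders(self, tmp_path, sim_data, sim_track):
        spec = gv.regionplot(sim_data, region="1:1000000-2000000", track=sim_track,
                             annotate=1e-6)
        out = tmp_path / "region.png"
        gv.render(spec, str(out))
        assert out.exists()


class TestBroadcast:
    def test_scalar_vector_and_mismatch(self):
        assert broadcast_option(1.0, 3, None) == [1.0, 1.0, 1.0]
        assert broadcast_option([1.0], 3, None) == [1.0, 1.0, 1.0]
        assert broadcast_option([1, 2, 3], 3, None) == [1, 2, 3]
        with pytest.raises(ValidationError):
            broadcast_option([1, 2], 3, None)

    def test_repel_separates_close_labels(self):
        labels = [Label(x=0.0, y=1.0, text="a"), Label(x=0.001, y=1.0, text="b")]
        out = repel_labels(labels, x_range=1.0)
        assert out[0].nudge_y != out[1].nudge_y
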