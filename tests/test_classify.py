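"""Hit filtering, syntenic context, presence and origin calling,
artefact triage and tandem detection."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from oscinova.classify import (
    ArtefactCategory,
    CandidateRecord,
    ContextResult,
    Origin,
    ParentInfo,
    PresenceStatus,
    call_presence,
    classify_artefact,
    classify_origin,
    count_novel_genes,
    detect_split_models,
    detect_tandem_copies,
    filter_hits,
    syntenic_context,
)
from oscinova.model import (
    AlignmentHit,
    GeneLocus,
    PipelineConfig,
    Strand,
)
from oscinova.simulate import default_panel


def hit(score, pid=95.0, chrom="chr1", start=0, end=500, species="s"):
    return AlignmentHit(query_id="q", subject_species=species,
                        subject_chrom=chrom, subject_start=start,
                        subject_end=end, subject_strand=Strand.PLUS,
                        score=float(score), percent_identity=pid)


def locus(gid, chrom="chr1", start=0, end=1000, gap=False, species="f"):
    return GeneLocus(species=species, chrom=chrom, start=start, end=end,
                     strand=Strand.PLUS, gene_id=gid, symbol=gid,
                     gap_flanked=gap)


class TestFilterHits:
    def test_threshold_is_strict(self, config):
        assert filter_hits([hit(50)], config) == []

    def test_empty(self, config):
        assert filter_hits([], config) == []

    def test_mixed_scores(self, config):
        kept = filter_hits([hit(12), hit(50), hit(51), hit(300)], config)
        assert sorted(h.score for h in kept) == [51.0, 300.0]

    @given(st.floats(50, 500))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_raising_threshold_never_adds_hits(self, thr):
        hits = [hit(s) for s in (10, 40, 50, 60, 120, 400)]
        base = {h.score for h in filter_hits(hits)}
        cfg = PipelineConfig(min_hit_score=thr)
        assert {h.score for h in filter_hits(hits, cfg)} <= base


class TestSyntenicContext:
    def subject_table(self):
        # six neighbours around a hit at [10_000, 11_000)
        names_up = ["u1", "u2", "u3"]      # nearest first, upstream
        names_dn = ["d1", "d2", "d3"]
        loci = []
        for i, n in enumerate(names_up):
            s = 9_000 - i * 1_000
            loci.append(locus(n, start=s, end=s + 500, species="s"))
        for i, n in enumerate(names_dn):
            s = 11_500 + i * 1_000
            loci.append(locus(n, start=s, end=s + 500, species="s"))
        return loci

    def test_all_flanks_match(self, config):
        r = syntenic_context(hit(100, start=10_000, end=11_000),
                             (["u1", "u2", "u3"], ["d1", "d2", "d3"]),
                             self.subject_table(), config)
        assert r.score == 1.0 and not r.limited

    def test_no_flanks_match(self, config):
        r = syntenic_context(hit(100, start=10_000, end=11_000),
                             (["x1", "x2", "x3"], ["y1", "y2", "y3"]),
                             self.subject_table(), config)
        assert r.score == 0.0

    def test_strand_agnostic_matching(self, config):
        # flanks given as if the subject region were inverted
        r = syntenic_context(hit(100, start=10_000, end=11_000),
                             (["d1", "d2", "d3"], ["u1", "u2", "u3"]),
                             self.subject_table(), config)
        assert r.score == 1.0

    def test_partial_neighbourhood_is_flagged(self, config):
        table = [g for g in self.subject_table() if g.gene_id != "u3"]
        r = syntenic_context(hit(100, start=10_000, end=11_000),
                             (["u1", "u2", "u3"], ["d1", "d2", "d3"]),
                             table, config)
        assert r.limited and r.score == pytest.approx(5 / 6)


class TestCallPresence:
    def test_no_hits_is_absent(self, config):
        call = call_presence("c", "s", [], [], config)
        assert call.status is PresenceStatus.ABSENT

    def test_good_hit_with_context_is_syntenic(self, config):
        call = call_presence("c", "s", [hit(120)],
                             [ContextResult(5 / 6)], config)
        assert call.status is PresenceStatus.PRESENT_SYNTENIC

    def test_good_hit_without_context_is_unplaced(self, config):
        call = call_presence("c", "s", [hit(120)], [ContextResult(0.0)],
                             config)
        assert call.status is PresenceStatus.PRESENT_UNPLACED

    def test_best_hit_tie_breaks(self, config):
        hits = [hit(120, start=5_000, end=5_400),
                hit(120, start=1_000, end=1_800),  # longer span wins
                hit(90, start=0, end=10_000)]
        call = call_presence("c", "s", hits, [ContextResult(1.0)] * 3, config)
        assert call.best_hit.subject_start == 1_000


def _matrix(present, panel):
    return {
        sp: (PresenceStatus.PRESENT_SYNTENIC if sp in present
             else PresenceStatus.ABSENT)
        for sp in panel.species
    }


@pytest.fixture(scope="module")
def panel():
    return default_panel()


class TestClassifyOrigin:
    @pytest.mark.parametrize("present_of,expected", [
        (lambda p: set(p.species), Origin.NOT_NOVEL),
        (lambda p: set(p.songbirds), Origin.SONGBIRD_UNIQUE),
        (lambda p: set(p.passerines), Origin.PASSERINE),
        (lambda p: {"zebra_finch"}, Origin.SINGLE_SPECIES_SUSPECT),
        (lambda p: set(p.finch_species), Origin.FINCH_SPECIFIC),
        (lambda p: set(p.avians) - set(p.galliforms),
         Origin.NEOAVES_OR_GALLIFORM_LOSS),
    ])
    def test_presence_patterns_map_to_origins(self, panel, present_of,
                                              expected):
        calls = classify_origin({"c": _matrix(present_of(panel), panel)},
                                panel, {"c": ParentInfo(family="c")})
        assert calls[0].origin is expected

    def test_incomplete_matrix_lists_missing_species(self, panel):
        row = _matrix(set(panel.songbirds), panel)
        row.pop("mouse")
        with pytest.raises(ValueError, match="mouse"):
            classify_origin({"c": row}, panel, {})

    def test_counting_rule_parent_undetermined_family(self, panel):
        # 3 indistinguishable copies -> 2 novel genes
        matrix = {f"A-{i}": _matrix(set(panel.songbirds), panel)
                  for i in range(3)}
        rule = {f"A-{i}": ParentInfo(family="A", parent_known=False)
                for i in range(3)}
        count = count_novel_genes(classify_origin(matrix, panel, rule))
        assert count.total == 2
        assert count.n_two_paralog_families == 1

    def test_counting_rule_known_parent_and_de_novo(self, panel):
        matrix = {"BL1": _matrix(set(panel.songbirds), panel),
                  "D": _matrix(set(panel.songbirds), panel)}
        rule = {"BL1": ParentInfo(family="B", parent_id="B", parent_known=True),
                "D": ParentInfo(family="D", de_novo=True)}
        count = count_novel_genes(classify_origin(matrix, panel, rule))
        assert count.total == 2
        assert count.n_single_paralog_families == 1
        assert count.n_de_novo == 1

    def test_max_missing_tolerates_dropout_in_focal_clade(self, panel):
        present = set(panel.songbirds) - {"american_crow"}
        calls = classify_origin({"c": _matrix(present, panel)}, panel,
                                {"c": ParentInfo(family="c")})
        assert calls[0].origin is Origin.FINCH_SPECIFIC


class TestArtefacts:
    def base(self, **kw):
        defaults = dict(candidate_id="c", locus=locus("c"))
        defaults.update(kw)
        return CandidateRecord(**defaults)

    def test_split_model(self):
        r = self.base(split_partner="c2")
        assert classify_artefact(r).category is ArtefactCategory.SPLIT_MODEL

    def test_detect_split_models_disjoint_query_coverage(self):
        cov = {
            "a": (locus("a", start=0, end=5_000), "ORTH1", (0, 200)),
            "b": (locus("b", start=6_000, end=12_000), "ORTH1", (200, 450)),
            "c": (locus("c", chrom="chr2"), "ORTH2", (0, 100)),
        }
        partners = detect_split_models(cov)
        assert partners == {"a": "b", "b": "a"}

    def test_tandem_and_interchrom_false_positives(self):
        r1 = self.base(subject_is_family_member=True, subject_same_chrom=True)
        r2 = self.base(subject_is_family_member=True, subject_same_chrom=False)
        assert classify_artefact(r1).category is \
            ArtefactCategory.TANDEM_FALSE_POSITIVE
        assert classify_artefact(r2).category is \
            ArtefactCategory.INTERCHROM_FALSE_POSITIVE

    def test_shared_duplication(self):
        r = self.base(shared_beyond_passerines=True)
        assert classify_artefact(r).category is \
            ArtefactCategory.SHARED_DUPLICATION

    def test_retrocopy_requires_intron_loss_and_repeats(self):
        r = self.base(intron_count=0, parent_intron_count=5,
                      repeat_flanked=True)
        assert classify_artefact(r).category is ArtefactCategory.RETROCOPY
        r2 = self.base(intron_count=0, parent_intron_count=5,
                       repeat_flanked=False)
        assert classify_artefact(r2).category is \
            ArtefactCategory.PASSES_CURATION

    def test_assembly_suspect_needs_tandem_gap_and_high_identity(self):
        r = self.base(locus=locus("c", gap=True), tandem=True,
                      best_hit=hit(80, pid=97.0))
        assert classify_artefact(r).category is \
            ArtefactCategory.ASSEMBLY_SUSPECT
        r2 = dataclasses.replace(r, best_hit=hit(80, pid=94.0))
        assert classify_artefact(r2).category is \
            ArtefactCategory.PASSES_CURATION

    def test_large_family_deferred(self):
        r = self.base(family_size=30)
        assert classify_artefact(r).category is \
            ArtefactCategory.LARGE_FAMILY_DEFERRED

    def test_categories_partition_candidates(self):
        records = [
            self.base(candidate_id="a", split_partner="x"),
            self.base(candidate_id="b", subject_is_family_member=True,
                      subject_same_chrom=True),
            self.base(candidate_id="c", shared_beyond_passerines=True),
            self.base(candidate_id="d", intron_count=0,
                      parent_intron_count=3, repeat_flanked=True),
            self.base(candidate_id="e"),
        ]
        calls = [classify_artefact(r) for r in records]
        assert len(calls) == len(records)  # exactly one category each
        passing = [c for c in calls
                   if c.category is ArtefactCategory.PASSES_CURATION]
        assert [c.candidate_id for c in passing] == ["e"]


class TestTandemDetection:
    def test_three_adjacent_copies_form_one_group(self):
        # three ~1 kb copies ~7 kb apart on one chromosome
        loci = [locus("A-1", chrom="chr1A", start=65_194_902, end=65_195_964),
                locus("A-2", chrom="chr1A", start=65_202_779, end=65_203_835),
                locus("A-3", chrom="chr1A", start=65_210_657, end=65_211_719)]
        groups = detect_tandem_copies(loci)
        assert [len(g) for g in groups] == [3]

    def test_copies_on_different_chromosomes_are_separate(self):
        loci = [locus("x", chrom="chr1"), locus("y", chrom="chr2")]
        assert [len(g) for g in detect_tandem_copies(loci)] == [1, 1]

    def test_spacing_above_cutoff_splits_groups(self):
        loci = [locus("x", start=0, end=1_000),
                locus("y", start=151_000, end=152_000)]  # 150 kb apart
        assert [len(g) for g in detect_tandem_copies(loci, 100_000)] == [1, 1]
        assert [len(g) for g in detect_tandem_copies(loci, 200_000)] == [2]
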