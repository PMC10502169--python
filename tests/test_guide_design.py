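"""Candidate enumeration, scoring, folding DP, ranking and the pipeline."""

import copy
import random

import pytest

from grnakit._seq import revcomp
from grnakit.genome_io import Contig, Genome, ValidationError, build_store
from grnakit.guide_design import (
    DEFAULT_SCAFFOLD,
    GuideCandidate,
    GuideParams,
    candidates_in_region,
    design,
    enumerate_pam_sites,
    nussinov_max_pairs,
    rank_and_select,
    score_folding,
    score_offtargets,
)
from grnakit.offtarget_search import OffTargetHit
from grnakit.region_select import RegionSpec, TargetRegion
from grnakit.simkit import SimSpec, plant_site, random_annotation, random_genome


def _region(seq, start=0, strand="+", locus="L1", contig="c1"):
    return TargetRegion(name=locus, contig_id=contig, start=start,
                        end=start + len(seq), strand=strand, seq=seq,
                        locus_id=locus)


# --------------------------------------------------------------- enumeration


def test_enumerate_pam_sites_hand_example():
    assert enumerate_pam_sites("ACGGTGGA", "NGG") == [(1, "+"), (4, "+")]


def test_enumerate_pam_sites_no_g():
    assert enumerate_pam_sites("T" * 40, "NGG") == []


def test_genome_ambiguity_never_matches_pam():
    # reverse-complement NGG is CCN, but a literal N in the sequence must not match
    assert enumerate_pam_sites("CCN", "NGG") == []


def test_candidate_geometry_23bp_region():
    random.seed(31)
    spacer = "".join(random.choice("ACGT") for _ in range(20))
    seq = spacer + "AGG"
    genome = Genome("t", [Contig("c1", "T" * 10 + seq + "T" * 10)])
    region = _region(seq, start=10)
    cands = candidates_in_region(region, genome, GuideParams())
    assert len(cands) == 1
    c = cands[0]
    assert (c.start, c.end, c.strand, c.spacer, c.pam_observed) == (10, 33, "+", spacer, "AGG")


def test_strand_filter_relative_to_locus():
    random.seed(32)
    spacer = "".join(random.choice("ACT") for _ in range(20))
    seq = spacer + "AGG"
    genome = Genome("t", [Contig("c1", seq)])
    plus_locus = _region(seq, strand="+")
    assert candidates_in_region(plus_locus, genome, GuideParams(strand_filter="template")) == []
    assert len(candidates_in_region(plus_locus, genome, GuideParams(strand_filter="coding"))) == 1
    minus_locus = _region(seq, strand="-")
    assert len(candidates_in_region(minus_locus, genome, GuideParams(strand_filter="template"))) == 1


def test_candidate_count_matches_sliding_window_oracle():
    rng = random.Random(33)
    params = GuideParams()
    L, P = params.spacer_len, len(params.pam)
    for _ in range(100):
        n = rng.randint(5, 120)
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        genome = Genome("t", [Contig("c1", seq)])
        region = _region(seq)
        expect = 0
        for s in range(0, n - L - P + 1):
            win = seq[s : s + L + P]
            if win[L + 1] == "G" and win[L + 2] == "G":
                expect += 1
            rc = revcomp(win)
            if rc[L + 1] == "G" and rc[L + 2] == "G":
                expect += 1
        assert len(candidates_in_region(region, genome, params)) == expect


def test_short_region_yields_nothing():
    genome = Genome("t", [Contig("c1", "ACGTAGGTTT")])
    assert candidates_in_region(_region("ACGTAGGTTT"), genome, GuideParams()) == []


# ------------------------------------------------------------------- scoring


def _cand(**kw):
    base = dict(locus_id="L1", contig_id="c1", start=0, end=23, strand="+",
                spacer="A" * 20, pam_observed="AGG")
    base.update(kw)
    return GuideCandidate(**base)


def _hit(start=500, positions=(), strand="+"):
    return OffTargetHit("c1", start, strand, tuple(positions), "AGG")


def test_offtarget_score_empty_is_zero():
    c = _cand()
    assert score_offtargets(c, []) == 0.0
    assert not c.perfect_offtarget


def test_offtarget_score_positional_weighting():
    c = _cand()
    score = score_offtargets(c, [_hit(positions=(1, 20))])
    assert score == pytest.approx(1.2 ** 1 + 1.2 ** 20)
    assert score == pytest.approx(39.5376, abs=5e-3)


def test_offtarget_score_additive_over_hits():
    c1, c2 = _cand(), _cand()
    one = score_offtargets(c1, [_hit(positions=(5, 12))])
    two = score_offtargets(c2, [_hit(positions=(5, 12)), _hit(start=900, positions=(5, 12))])
    assert two == pytest.approx(2 * one)


def test_perfect_match_offtarget_flags_candidate():
    c = _cand()
    score_offtargets(c, [_hit(positions=())])
    assert c.perfect_offtarget


# ------------------------------------------------------------------- folding


def _enum_max_pairs(s):
    """Exhaustive enumeration over all non-crossing structures (oracle)."""
    s = s.upper().replace("U", "T")
    ok = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}

    def best(positions):
        if len(positions) < 2:
            return 0
        i = positions[0]
        top = best(positions[1:])
        for idx in range(1, len(positions)):
            j = positions[idx]
            if j - i > 3 and (s[i], s[j]) in ok:
                top = max(top, 1 + best(positions[1:idx]) + best(positions[idx + 1:]))
        return top

    return best(tuple(range(len(s))))


def test_poly_a_spacer_fully_accessible():
    assert score_folding("A" * 20, "AAAA") == 1.0


def test_complementary_spacer_partially_paired():
    spacer = revcomp(DEFAULT_SCAFFOLD[:20]).replace("U", "T")
    assert score_folding(spacer, DEFAULT_SCAFFOLD) < 1.0


def test_nussinov_equals_exhaustive_enumeration():
    rng = random.Random(34)
    for _ in range(60):
        n = rng.randint(1, 12)
        s = "".join(rng.choice("ACGU") for _ in range(n))
        npairs, paired = nussinov_max_pairs(s)
        assert npairs == _enum_max_pairs(s)
        assert len(paired) == 2 * npairs


def test_traceback_structure_is_valid():
    rng = random.Random(35)
    ok = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}
    for _ in range(20):
        s = "".join(rng.choice("ACGT") for _ in range(40))
        npairs, paired = nussinov_max_pairs(s)
        assert len(paired) == 2 * npairs


# ------------------------------------------------------------------- ranking


def test_top_n_selected_with_ranks():
    cands = [_cand(start=i * 30, end=i * 30 + 23, fold_score=0.5) for i in range(5)]
    lib = rank_and_select(cands, GuideParams(n_guides=3))
    assert len(lib.guides) == 3
    assert [g.rank for g in lib.guides] == [1, 2, 3]
    assert [g.name for g in lib.guides] == ["L1_T1", "L1_T2", "L1_T3"]
    assert lib.shortfall == {}


def test_shortfall_records_achieved_count():
    lib = rank_and_select([_cand()], GuideParams(n_guides=3))
    assert lib.shortfall == {"L1": 1}
    assert len(lib.guides) == 1


def test_coordinate_tie_break_is_stable():
    a = _cand(start=100, end=123)
    b = _cand(start=40, end=63)
    for order in ([a, b], [b, a]):
        lib = rank_and_select([copy.deepcopy(c) for c in order], GuideParams(n_guides=1))
        assert lib.guides[0].start == 40


def test_permuting_input_leaves_selection_identical():
    rng = random.Random(36)
    cands = []
    for i in range(12):
        c = _cand(start=i * 40, end=i * 40 + 23,
                  fold_score=rng.choice([0.3, 0.6, 0.9]))
        score_offtargets(c, [_hit(start=2000 + j * 50, positions=(rng.randint(1, 20),))
                             for j in range(rng.randint(0, 3))])
        cands.append(c)
    baseline = None
    for seed in range(4):
        shuffled = [copy.deepcopy(c) for c in cands]
        random.Random(seed).shuffle(shuffled)
        lib = rank_and_select(shuffled, GuideParams(n_guides=3))
        snapshot = [(g.name, g.start, g.rank) for g in lib.guides]
        baseline = baseline or snapshot
        assert snapshot == baseline


def test_extra_offtarget_never_improves_rank():
    clean = _cand(start=40, end=63, fold_score=0.5)
    dirty = _cand(start=100, end=123, fold_score=0.5)
    score_offtargets(dirty, [_hit(positions=(10,))])
    lib = rank_and_select([dirty, clean], GuideParams(n_guides=2))
    assert lib.guides[0].start == 40


def test_perfect_offtarget_candidates_fill_last():
    clean = _cand(start=100, end=123)
    flagged = _cand(start=40, end=63)
    score_offtargets(flagged, [_hit(positions=())])
    lib = rank_and_select([flagged, clean], GuideParams(n_guides=2))
    assert [g.start for g in lib.guides] == [100, 40]
    assert lib.guides[1].perfect_offtarget
    assert lib.shortfall == {"L1": 1}  # only one clean guide existed


# ------------------------------------------------------------------ pipeline


def test_design_end_to_end_self_consistent(sim20k, tmp_path):
    genome, store = sim20k
    params = GuideParams()
    lib, paths = design(genome, store, None, RegionSpec(), params,
                        out_prefix=tmp_path / "run")
    assert lib.guides, "expected at least one guide"
    per_locus = {}
    for g in lib.guides:
        per_locus[g.locus_id] = per_locus.get(g.locus_id, 0) + 1
        window = genome[g.contig_id].seq[g.start : g.end]
        if g.strand == "-":
            window = revcomp(window)
        assert window == g.spacer + g.pam_observed
        assert g.end - g.start == params.spacer_len + len(params.pam)
    assert all(v <= params.n_guides for v in per_locus.values())
    # every locus lands in results or in the report
    reported = set(lib.shortfall) | set(per_locus)
    assert reported >= set(store.list_loci())
    for key in ("results", "target_regions", "report", "scoring_log"):
        assert paths[key].exists()


def test_design_duplicated_locus_flagged_and_shortfalled():
    spec = SimSpec(contig_len=12_000, n_genes=4, gene_len=(300, 500),
                   intergenic=(200, 300), seed=77)
    genome = random_genome(spec)
    feats = random_annotation(genome, spec)
    store = build_store(feats)
    # duplicate the first gene's whole neighbourhood elsewhere in the genome
    first = next(f for f in feats if f.ftype == "CDS")
    block = genome.contigs[0].seq[first.start - 50 : first.end + 50]
    genome = plant_site(genome, block, 9000)
    lib, _ = design(genome, store, [first.locus_id], RegionSpec(), GuideParams())
    assert lib.guides, "duplicated locus should still emit flagged guides"
    assert all(g.perfect_offtarget for g in lib.guides if g.locus_id == first.locus_id)
    assert lib.shortfall.get(first.locus_id) == 0


def test_design_rejects_invalid_spec(sim20k):
    genome, store = sim20k
    bad = RegionSpec(limit_mode="coding_only", start_anchor="feature_start",
                     start_offset=-100, end_anchor="feature_end", end_offset=0)
    with pytest.raises(ValidationError, match="region spec"):
        design(genome, store, None, bad, GuideParams())


def test_design_zero_resolved_loci_errors(sim20k):
    genome, store = sim20k
    with pytest.raises(ValidationError, match="no target regions"):
        design(genome, store, ["ABSENT"], RegionSpec(), GuideParams())


def test_params_validation():
    with pytest.raises(ValidationError):
        GuideParams(spacer_len=5)
    with pytest.raises(ValidationError):
        GuideParams(n_guides=0)
    with pytest.raises(ValidationError):
        GuideParams(pam="NQG")
    with pytest.raises(ValidationError):
        GuideParams(strand_filter="bogus")
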