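"""Cassette discovery: anchors, windows, role assignment, classification."""

import dataclasses

import pytest

from polyprospect.cassette_mining import (
    CassetteCall,
    MiningConfig,
    Window,
    assign_roles,
    classify_cassette,
    extract_window,
    find_seed_hits,
    mine_genome,
    rescue_split,
    write_calls_tsv,
)
from polyprospect.io_formats import (
    Contig,
    GeneFeature,
    Genome,
    reverse_complement_genome,
)
from polyprospect.synthetic_data import (
    CassetteSpec,
    VARIANT_EXPECTED,
    mutate_protein,
    plant_cassette,
)

VARIANTS = list(VARIANT_EXPECTED)


# ---------------------------------------------------------------------------
# anchors and windows
# ---------------------------------------------------------------------------

def test_seed_hit_is_planted_anchor_desaturase(role_queries, mining_config):
    g, truth = plant_cassette(CassetteSpec("polyyne_full"), seed=2,
                              queries=role_queries)
    anchors = find_seed_hits(g, role_queries.roles["DES_B"], mining_config)
    assert [a.gene_id for a in anchors] == [truth.role_genes["DES_B"]]


def test_no_anchors_in_decoy_only_genome(role_queries, mining_config):
    g, _ = plant_cassette(CassetteSpec("none"), seed=2, queries=role_queries)
    assert find_seed_hits(g, role_queries.roles["DES_B"], mining_config) == []


def test_two_cassettes_on_different_contigs_give_two_anchors(role_queries,
                                                             mining_config):
    g1, t1 = plant_cassette(CassetteSpec("polyyne_full"), seed=3, n_contigs=1,
                            queries=role_queries, genome_id="gA")
    g2, t2 = plant_cassette(CassetteSpec("alkyne_only"), seed=4, n_contigs=1,
                            queries=role_queries, genome_id="gB")
    merged = Genome("multi", g1.contigs + g2.contigs, g1.features + g2.features)
    anchors = find_seed_hits(merged, role_queries.roles["DES_B"], mining_config)
    assert {a.gene_id for a in anchors} == {t1.role_genes["DES_B"],
                                            t2.role_genes["DES_B"]}


def test_window_arithmetic_and_edge_flags(mining_config):
    contig = Contig("c1", "A" * 200_000)
    mid = GeneFeature("mid", "c1", 50_000, 51_000, "+", protein="M")
    near = GeneFeature("near", "c1", 5_000, 6_000, "+", protein="M")
    g = Genome("g", [contig], [mid, near])
    w = extract_window(g, mid, mining_config)
    assert (w.start, w.end) == (20_000, 81_000)
    assert not w.left_edge_truncated and not w.right_edge_truncated
    w2 = extract_window(g, near, mining_config)
    assert (w2.start, w2.end) == (1, 36_000)
    assert w2.left_edge_truncated and not w2.right_edge_truncated


def test_window_contains_all_planted_cassette_genes(role_queries, mining_config):
    g, truth = plant_cassette(CassetteSpec("polyyne_full"), seed=5,
                              queries=role_queries)
    anchor = g.feature(truth.role_genes["DES_B"])
    w = extract_window(g, anchor, mining_config)
    member_ids = {f.gene_id for f in w.members}
    assert set(truth.role_genes.values()) <= member_ids


# ---------------------------------------------------------------------------
# role assignment
# ---------------------------------------------------------------------------

def test_assign_roles_full_and_triad(role_queries, mining_config):
    for variant, expected_roles in [
        ("polyyne_full", {"FAAL", "DES_B", "ACP", "DES_2", "DES_3", "TE", "RUB"}),
        ("alkyne_only", {"FAAL", "DES_B", "ACP"}),
    ]:
        g, truth = plant_cassette(CassetteSpec(variant), seed=6,
                                  queries=role_queries)
        w = extract_window(g, g.feature(truth.role_genes["DES_B"]), mining_config)
        got = assign_roles(w, role_queries, mining_config)
        assert {a.role for a in got} == expected_roles
        assert all(a.gene_id == truth.role_genes[a.role] for a in got)


def test_gene_consumed_by_one_role_only(role_queries, mining_config):
    """A single desaturase gene cannot satisfy both DES_2 and DES_3."""
    des2 = mutate_protein(role_queries.roles["DES_2"], 0.9, seed=1)
    feats = [GeneFeature("only_des", "c1", 1000, 2000, "+", protein=des2)]
    w = Window("g", "c1", 1, 40_000, "only_des", tuple(feats), False, False)
    got = assign_roles(w, {"DES_2": role_queries.roles["DES_2"],
                           "DES_3": role_queries.roles["DES_2"]}, mining_config)
    assert len(got) == 1  # the second role finds no distinct gene


# ---------------------------------------------------------------------------
# classification decision table
# ---------------------------------------------------------------------------

def _call_for(role_queries, mining_config, variant, seed=7, **spec_kw):
    g, truth = plant_cassette(CassetteSpec(variant, **spec_kw), seed=seed,
                              queries=role_queries)
    calls = mine_genome(g, role_queries, mining_config)
    return g, truth, calls


@pytest.mark.parametrize("variant", VARIANTS)
def test_decision_table_on_planted_variants(role_queries, mining_config, variant):
    g, truth, calls = _call_for(role_queries, mining_config, variant)
    if truth.expected == "none":
        assert calls == []
    else:
        assert [c.classification for c in calls] == [truth.expected]


def test_polyyne_call_reports_exactly_seven_roles(role_queries, mining_config):
    _, _, calls = _call_for(role_queries, mining_config, "polyyne_full")
    assert len(calls[0].assignments) == 7


def test_alkyne_call_reports_exactly_three_roles(role_queries, mining_config):
    _, _, calls = _call_for(role_queries, mining_config, "alkyne_only")
    assert len(calls[0].assignments) == 3


def test_truth_table_recovery_variants_by_seeds(role_queries, mining_config):
    """Every variant x seed combination classifies to its planted truth."""
    for variant in VARIANTS:
        for seed in (101, 102):
            g, truth = plant_cassette(CassetteSpec(variant), seed=seed,
                                      queries=role_queries)
            calls = mine_genome(g, role_queries, mining_config)
            got = calls[0].classification if calls else "none"
            assert got == truth.expected, (variant, seed)


def test_tightening_thresholds_only_degrades_calls(role_queries):
    rank = {"none": 0, "alkyne": 1, "polyyne_split": 2, "polyyne_norub": 2,
            "polyyne_p450_variant": 2, "polyyne": 2}
    g, _ = plant_cassette(CassetteSpec("polyyne_full"), seed=8,
                          queries=role_queries)
    loose = mine_genome(g, role_queries, MiningConfig())
    tight = mine_genome(g, role_queries, MiningConfig(
        seed_e_threshold=1e-200, desaturase_e_threshold=1e-250,
        accessory_e_threshold=1e-200, acp_e_threshold=1e-200))
    worst_tight = max((rank[c.classification] for c in tight), default=0)
    best_loose = max((rank[c.classification] for c in loose), default=0)
    assert worst_tight <= best_loose


def test_strand_invariance(role_queries, mining_config):
    g, truth = plant_cassette(CassetteSpec("polyyne_full"), seed=9,
                              queries=role_queries)
    flipped = reverse_complement_genome(g)
    a = [c.classification for c in mine_genome(g, role_queries, mining_config)]
    b = [c.classification for c in mine_genome(flipped, role_queries, mining_config)]
    assert a == b == ["polyyne"]


def test_window_containment_of_called_roles(role_queries, mining_config):
    g, _ = plant_cassette(CassetteSpec("polyyne_full"), seed=10,
                          queries=role_queries)
    (call,) = mine_genome(g, role_queries, mining_config)
    for a in call.assignments:
        f = g.feature(a.gene_id)
        assert f.contig_id == call.window.contig_id
        assert f.end >= call.window.start and f.start <= call.window.end


# ---------------------------------------------------------------------------
# split rescue
# ---------------------------------------------------------------------------

def test_split_cassette_rescued_across_contigs(role_queries, mining_config):
    g, truth, calls = _call_for(role_queries, mining_config, "split")
    (call,) = calls
    assert call.classification == "polyyne_split"
    te_contig = g.feature(truth.role_genes["TE"]).contig_id
    assert call.rescue_contigs == (te_contig,)
    assert len(call.assignments) == 7


def test_edge_flagged_partial_without_remote_roles_stays_alkyne(role_queries,
                                                                mining_config):
    g, truth = plant_cassette(CassetteSpec("split"), seed=12,
                              queries=role_queries)
    # delete the far-contig TE/RUB genes: rescue must find nothing
    far = {truth.role_genes["TE"], truth.role_genes["RUB"]}
    g.features = [f for f in g.features if f.gene_id not in far]
    (call,) = mine_genome(g, role_queries, mining_config)
    assert call.classification == "alkyne"
    assert call.rescue_contigs == ()


def test_remote_roles_far_from_contig_ends_not_rescued(role_queries,
                                                       mining_config):
    g, truth = plant_cassette(CassetteSpec("split"), seed=14,
                              genome_size=200_000, queries=role_queries)
    # move the far-contig genes to the middle, >30 kbp from both ends
    moved = []
    for f in g.features:
        if f.gene_id in (truth.role_genes["TE"], truth.role_genes["RUB"]):
            shift = 45_000
            f = dataclasses.replace(f, start=f.start + shift, end=f.end + shift)
        moved.append(f)
    contig2 = g.contigs[1]
    for f in moved:
        if f.gene_id in (truth.role_genes["TE"], truth.role_genes["RUB"]):
            assert f.start > 30_000 and f.end < len(contig2) - 30_000
    g = Genome(g.genome_id, g.contigs, moved)
    (call,) = mine_genome(g, role_queries, mining_config)
    assert call.classification == "alkyne"


def test_calls_tsv_is_written(tmp_path, role_queries, mining_config):
    _, _, calls = _call_for(role_queries, mining_config, "polyyne_full")
    out = tmp_path / "calls.tsv"
    write_calls_tsv(calls, out)
    lines = out.read_text().strip().split("\n")
    assert lines[0].startswith("genome_id\t")
    assert "\tpolyyne\t" in lines[1]
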