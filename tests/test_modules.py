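"""DEG calling, module classification, and gene-set enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from citmap.modules import (
    ExpressionMatrix,
    call_degs,
    classify_modules,
    enrichment_score,
    enrichment_table,
    module_counts,
    permutation_nes,
    read_expression,
    read_gmt,
)


def make_matrix(genes, vehicle, fibrinogen, cit_fibrinogen, donors=("d1", "d2")):
    """Rows per gene: one value per donor for each condition."""
    data = {}
    for cond, block in (
        ("vehicle", vehicle),
        ("fibrinogen", fibrinogen),
        ("cit_fibrinogen", cit_fibrinogen),
    ):
        for j, donor in enumerate(donors):
            data[(cond, donor)] = [row[j] for row in block]
    values = pd.DataFrame(data, index=list(genes))
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["condition", "donor"])
    return ExpressionMatrix(values)


def test_deg_directions_and_concordance():
    expr = make_matrix(
        ["up", "disc", "flat"],
        vehicle=[(0, 0), (0, 0), (0, 0)],
        fibrinogen=[(2.0, 1.5), (2.0, -2.0), (0.0, 0.0)],
        cit_fibrinogen=[(2.0, 1.5), (0.0, 0.0), (0.0, 0.0)],
    )
    calls = {c.gene: c for c in call_degs(expr, fc_threshold=1.0)}
    assert calls["up"].concordant == "UP"
    assert calls["disc"].concordant == "discordant"
    assert calls["disc"].per_donor == ("UP", "DN")
    assert calls["flat"].concordant == "NC"


def test_all_zero_matrix_is_all_nc():
    expr = make_matrix(["a", "b"], [(0, 0)] * 2, [(0, 0)] * 2, [(0, 0)] * 2)
    assert all(c.concordant == "NC" for c in call_degs(expr, 1.0))


def test_missing_condition_for_a_donor_errors():
    values = pd.DataFrame(
        {("vehicle", "d1"): [0.0], ("fibrinogen", "d1"): [1.0]}, index=["g"]
    )
    values.columns = pd.MultiIndex.from_tuples(values.columns)
    with pytest.raises(ValueError, match="missing conditions"):
        ExpressionMatrix(values)


def test_module_classification_rules():
    expr = make_matrix(
        ["m2", "m1", "m3", "same", "m2dn"],
        vehicle=[(0, 0)] * 5,
        fibrinogen=[(2, 2), (2, 2), (-2, -2), (2, 2), (-2, -2)],
        cit_fibrinogen=[
            (0.5, 0.8),   # reversal -1.5, -1.2  -> module2
            (1.9, 2.2),   # cit delta -0.1, +0.2 -> module1
            (-2.1, -1.8), # no reversal          -> module3
            (3.5, 3.6),   # same-direction change -> none
            (0.0, -0.5),  # DN reversed (+2, +1.5) -> module2
        ],
    )
    degs = call_degs(expr, 1.0)
    labels = {l.gene: l.module for l in classify_modules(degs, expr, 1.0)}
    assert labels == {
        "m2": "module2",
        "m1": "module1",
        "m3": "module3",
        "same": "none",
        "m2dn": "module2",
    }
    counts = module_counts(classify_modules(degs, expr, 1.0))
    assert sum(counts.values()) == 5


def test_reversal_needs_every_donor():
    expr = make_matrix(
        ["twothirds"],
        vehicle=[(0, 0, 0)],
        fibrinogen=[(2, 2, 2)],
        cit_fibrinogen=[(0.5, 0.5, 2.0)],  # reversed in two of three donors
        donors=("d1", "d2", "d3"),
    )
    degs = call_degs(expr, 1.0)
    assert classify_modules(degs, expr, 1.0)[0].module == "module1"
    assert classify_modules(degs, expr, 1.0, majority_vote=True)[0].module == "module2"


def test_classify_errors_on_absent_gene():
    expr = make_matrix(["g"], [(0, 0)], [(2, 2)], [(0, 0)])
    degs = call_degs(expr, 1.0)
    ghost = [d.__class__("ghost", d.per_donor, d.concordant) for d in degs]
    with pytest.raises(KeyError):
        classify_modules(ghost, expr, 1.0)


def test_labels_invariant_to_gene_and_donor_order():
    rng = np.random.default_rng(5)
    n = 60
    genes = [f"g{i}" for i in range(n)]
    expr = make_matrix(
        genes,
        vehicle=rng.normal(0, 0.2, (n, 2)),
        fibrinogen=rng.normal(0, 2.0, (n, 2)),
        cit_fibrinogen=rng.normal(0, 2.0, (n, 2)),
    )
    base = {l.gene: l.module for l in classify_modules(call_degs(expr, 1.0), expr, 1.0)}
    shuffled_vals = expr.values.sample(frac=1, random_state=1)
    shuffled_vals = shuffled_vals[
        [(c, d) for c in ("cit_fibrinogen", "vehicle", "fibrinogen") for d in ("d2", "d1")]
    ]
    shuffled = ExpressionMatrix(shuffled_vals)
    redo = {l.gene: l.module for l in classify_modules(call_degs(shuffled, 1.0), shuffled, 1.0)}
    assert redo == base


# --- enrichment -------------------------------------------------------------


def ks_oracle(ordered_genes, gene_set):
    """Classical two-list KS running statistic, plain-Python reference."""
    hits = [g in gene_set for g in ordered_genes]
    n_hit = sum(hits)
    n_miss = len(hits) - n_hit
    best = 0.0
    run = 0.0
    for h in hits:
        run += 1.0 / n_hit if h else -1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


def ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(0, 1, n))[::-1]
    return [(f"g{i}", float(s)) for i, s in enumerate(scores)]


def test_weight_zero_matches_ks_oracle():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = rng.integers(5, 51)
        lst = ranked(int(n), seed=int(rng.integers(1 << 30)))
        size = int(rng.integers(1, n))
        members = {f"g{i}" for i in rng.choice(int(n), size=size, replace=False)}
        es = enrichment_score(lst, members, weight=0.0)
        assert es == pytest.approx(ks_oracle([g for g, _ in lst], members), abs=1e-12)
        assert abs(es) <= 1.0


def test_top_loaded_set_scores_positive():
    lst = ranked(100)
    assert enrichment_score(lst, {g for g, _ in lst[:10]}, weight=0.0) > 0.5


def test_interleaved_set_scores_near_zero():
    lst = ranked(1000, seed=3)
    members = {g for i, (g, _) in enumerate(lst) if i % 10 == 0}
    assert abs(enrichment_score(lst, members, weight=0.0)) < 0.06


def test_complement_ordering_flips_sign():
    lst = ranked(40, seed=9)
    members = {g for g, _ in lst[:8]}
    forward = enrichment_score(lst, members, weight=0.0)
    reverse = enrichment_score(lst[::-1], members, weight=0.0)
    assert forward == pytest.approx(-reverse, abs=1e-12)


def test_empty_intersection_errors():
    with pytest.raises(ValueError, match="empty intersection"):
        enrichment_score(ranked(10), {"absent"}, weight=0.0)


def test_planted_set_nes_and_fdr():
    lst = ranked(500, seed=21)
    members = {g for g, _ in lst[:25]}
    es = enrichment_score(lst, members, weight=1.0)
    res = permutation_nes(es, lst, members, n_perm=1000, seed=4, weight=1.0)
    assert res.nes > 1.0
    assert res.fdr_q < 0.25
    again = permutation_nes(es, lst, members, n_perm=1000, seed=4, weight=1.0)
    assert again == res  # fixed-seed reproducibility


def test_null_fdr_q_approximately_uniform():
    """Random gene sets against random rankings should give q-values with
    no tail concentration (the permutation null is well calibrated)."""
    rng = np.random.default_rng(31)
    qs = []
    for _ in range(200):
        lst = ranked(100, seed=int(rng.integers(1 << 30)))
        members = {f"g{i}" for i in rng.choice(100, size=10, replace=False)}
        es = enrichment_score(lst, members, weight=1.0)
        res = permutation_nes(es, lst, members, n_perm=100, seed=int(rng.integers(1 << 30)))
        qs.append(res.fdr_q)
    qs = np.asarray(qs)
    assert 0.35 < qs.mean() < 0.65
    assert stats.kstest(qs, "uniform").statistic < 0.15


def test_enrichment_table_and_io(tmp_path):
    gmt = tmp_path / "sets.gmt"
    gmt.write_text("top\tdesc\tg0\tg1\tg2\tg3\nmid\tdesc\tg40\tg50\tg60\n")
    sets = read_gmt(gmt)
    assert set(sets) == {"top", "mid"}
    table = enrichment_table(ranked(100, seed=2), sets, n_perm=100, seed=1)
    assert list(table.index) == ["top", "mid"]
    assert table.loc["top", "es"] > table.loc["mid", "es"]
    assert ((table["fdr_q"] >= 0) & (table["fdr_q"] <= 1)).all()


def test_read_expression_roundtrip(tmp_path):
    expr = make_matrix(["g1", "g2"], [(0, 0)] * 2, [(2, 2)] * 2, [(0, 0)] * 2)
    flat = expr.values.copy()
    flat.columns = [f"{c}_{d}" for c, d in flat.columns]
    expr_path = tmp_path / "expr.csv"
    flat.to_csv(expr_path)
    design = pd.DataFrame(
        {
            "sample": flat.columns,
            "condition": [c for c, _ in expr.values.columns],
            "donor": [d for _, d in expr.values.columns],
        }
    )
    design_path = tmp_path / "design.csv"
    design.to_csv(design_path, index=False)
    loaded = read_expression(expr_path, design_path)
    assert {c.gene: c.concordant for c in call_degs(loaded, 1.0)} == {
        "g1": "UP",
        "g2": "UP",
    }
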