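"""Gene-set enrichment of the three modules against a citrullination-
reversal ranking.

Genes are ranked by how strongly citrullinated fibrinogen opposes the
fibrinogen-induced change (sign-adjusted mean across donors); each module
from 03 is then scored as a gene set with the permutation-normalized
running-sum statistic.  Module 2 — the genes whose fibrinogen response is
reversed by citrullination — is the only module expected to be enriched.

Writes results/enrichment.tsv.
"""

from pathlib import Path

import numpy as np

from citmap.modules import call_degs, classify_modules, enrichment_table
from citmap.simulate import ExpressionSimConfig, simulate_expression

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    expr, _ = simulate_expression(ExpressionSimConfig(seed=SEED))
    degs = call_degs(expr, fc_threshold=1.0)
    labels = classify_modules(degs, expr, reversal_threshold=1.0)

    fib = expr.delta("fibrinogen", "vehicle").mean(axis=1)
    reversal = -np.sign(fib) * expr.delta("cit_fibrinogen", "fibrinogen").mean(axis=1)
    ranking = sorted(zip(expr.genes, reversal), key=lambda t: -t[1])
    sets = {
        module: {l.gene for l in labels if l.module == module}
        for module in ("module1", "module2", "module3")
    }
    table = enrichment_table(ranking, sets, n_perm=1000, seed=SEED)
    table.to_csv(OUT / "enrichment.tsv", sep="\t")
    print(table.round(4).to_string())
    print(
        "\nOnly module 2 concentrates at the top of the reversal ranking "
        "(positive NES, low FDR-q); modules 1 and 3 do not."
    )


if __name__ == "__main__":
    main()
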