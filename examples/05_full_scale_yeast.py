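"""Full-scale run on a genome-scale yeast model (optional; needs downloads).

Reproduces the genome-scale workflow on user-supplied inputs: the yeast
7.6 SBML reconstruction, turnover-number and molecular-weight TSV tables,
a growth-medium JSON, and an experimental interaction-call TSV in this
package's dialect.  None of these files ship with the package; expect the
all-pairs stage to take hours (four methods x ~70k pair LP solves).

Usage:
    python examples/05_full_scale_yeast.py --model yeast_7.6.xml \
        --kcat kcat.tsv --mw mw.tsv --medium medium.json \
        --observed calls.tsv --method ccFBA --out results/
"""

import argparse
import pathlib

from epistanet import (
    EnzymeCostParams,
    apply_medium,
    apply_strain_background,
    impute_kcats,
    load_kcat_table,
    load_medium,
    load_mw_table,
    read_experimental_calls,
    read_sbml,
    run_all_pairs,
    screen_nonessential_unblocked_genes,
    sweep_cutoffs,
    write_records,
)
from epistanet.evaluation import default_cutoff_grid

STRAIN_BACKGROUND = ["CAN1", "LYP1", "URA3", "LEU2", "MET17"]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--model", required=True)
    ap.add_argument("--kcat")
    ap.add_argument("--mw")
    ap.add_argument("--medium")
    ap.add_argument("--observed")
    ap.add_argument("--method", default="ccFBA",
                    choices=["FBA", "lMOMA", "MOMENT", "ccFBA"])
    ap.add_argument("--C", type=float, default=0.27)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    model = read_sbml(args.model)
    model = apply_strain_background(model, STRAIN_BACKGROUND)
    if args.medium:
        model = apply_medium(model, load_medium(args.medium))
    print(f"prepared model: {len(model.genes)} genes, {len(model.reactions)} reactions")

    params = None
    if args.method in ("MOMENT", "ccFBA"):
        kcat = impute_kcats(load_kcat_table(args.kcat) if args.kcat else {}, model)
        mw = load_mw_table(args.mw) if args.mw else None
        params = EnzymeCostParams.from_tables(model, kcat, mw, C=args.C)

    genes = sorted(screen_nonessential_unblocked_genes(model))
    n_pairs = len(genes) * (len(genes) - 1) // 2
    print(f"screened gene set: {len(genes)} genes -> {n_pairs} pairs")

    records = run_all_pairs(model, args.method, genes, params=params)
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    write_records(records, out / f"epistasis_{args.method}.csv")

    counts = {}
    for r in records:
        counts[r.interaction_class] = counts.get(r.interaction_class, 0) + 1
    print(f"{args.method}: {counts.get('negative', 0)} negative, "
          f"{counts.get('positive', 0)} positive interactions")

    if args.observed:
        calls = read_experimental_calls(args.observed)
        for sign in ("negative", "positive"):
            curve = sweep_cutoffs(records, calls, default_cutoff_grid(), sign, n_pairs)
            curve.rows.to_csv(out / f"metrics_{args.method}_{sign}.csv", index=False)
        print(f"wrote precision/recall sweeps to {out}/")


if __name__ == "__main__":
    main()
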