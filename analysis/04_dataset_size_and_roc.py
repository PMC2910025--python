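"""Dataset-size sweep and ROC analysis of active/inactive discrimination.

Trains models on decreasing fractions of the panel (pairs or whole kinases)
and evaluates on the remainder, repeated over random splits; then contrasts
ROC curves of a model trained on 80% vs 10% of the kinases.

Writes results/size_sweep.tsv and results/roc_points.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from kinopcm import SyntheticConfig, generate_dataset
from kinopcm.descriptors import describe_set
from kinopcm.models import make_method
from kinopcm.preprocessing import DesignBuilder
from kinopcm.validation import dataset_size_sweep, roc_analysis


def _train_fraction_roc(builder, method, frac, seed):
    rng = np.random.default_rng(seed)
    n_kin = len(builder.kinase_ids)
    train_kin = rng.choice(n_kin, size=max(int(round(frac * n_kin)), 2),
                           replace=False)
    train_rows = np.flatnonzero(np.isin(builder.k_idx, train_kin))
    test_rows = np.setdiff1d(np.arange(builder.n_rows), train_rows)
    fold = builder.fit_fold(train_rows, cross=method.needs_cross)
    hp = method.grid()[len(method.grid()) // 2]
    pred = method.fit_predict(fold, train_rows, test_rows, hp)
    return roc_analysis(builder.y[test_rows], pred)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-kinases", type=int, default=80)
    parser.add_argument("--n-inhibitors", type=int, default=20)
    parser.add_argument("--n-repeats", type=int, default=3)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    ds = generate_dataset(SyntheticConfig(
        seed=args.seed, n_kinases=args.n_kinases,
        n_inhibitors=args.n_inhibitors,
    ))
    kin_block = describe_set(ds.msa, "aligned_z")
    builder = DesignBuilder(ds.ligand_table, kin_block, ds.activity)
    args.out_dir.mkdir(parents=True, exist_ok=True)

    tables = []
    for name in ("knn", "pls_x"):
        for mode in ("pairwise", "kinasewise"):
            sweep = dataset_size_sweep(
                builder, make_method(name),
                fractions=(0.8, 0.6, 0.4, 0.2, 0.1),
                n_repeats=args.n_repeats, mode=mode, seed=args.seed,
            )
            sweep.insert(0, "method", name)
            sweep.insert(1, "mode", mode)
            tables.append(sweep)
            trend = " -> ".join(f"{v:.2f}" for v in sweep["metric_mean"])
            print(f"{name} {mode}: P2 over fractions 0.8..0.1: {trend}")
    sweep_df = pd.concat(tables, ignore_index=True)
    sweep_df.to_csv(args.out_dir / "size_sweep.tsv", sep="\t", index=False)

    roc_rows = []
    for frac in (0.8, 0.1):
        roc = _train_fraction_roc(builder, make_method("pls_x"), frac,
                                  args.seed)
        spec80 = roc["specificity_at_sensitivity"][0.80]
        print(f"pls_x trained on {int(frac * 100)}% of kinases: "
              f"AUC={roc['auc']:.3f}, specificity at sensitivity 0.80: "
              f"{spec80:.3f}")
        roc_rows.append(pd.DataFrame({
            "train_fraction": frac, "fpr": roc["fpr"], "tpr": roc["tpr"],
        }))
    pd.concat(roc_rows, ignore_index=True).to_csv(
        args.out_dir / "roc_points.tsv", sep="\t", index=False
    )
    print(f"tables -> {args.out_dir}/size_sweep.tsv, "
          f"{args.out_dir}/roc_points.tsv")


if __name__ == "__main__":
    main()
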