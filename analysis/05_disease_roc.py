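#!/usr/bin/env python
"""Disease cohorts and biomarker discrimination: apply the calibrated
diabetic / hypertensive stage multipliers to filtered healthy subjects,
re-simulate, and compare RI vs single-kidney renal blood flow as
classifiers of the nephropathy etiology (ROC, Youden cut-offs)."""

import argparse
import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from renalpulse.pipeline import StudyConfig, cmd_disease_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-per-group", type=int, default=24,
                    help="healthy subjects in the 50-59 group")
    ap.add_argument("--outdir", default="results/05_disease")
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO)

    cfg = StudyConfig(seed=args.seed, output_dir=args.outdir,
                      n_per_group={"50-59": args.n_per_group},
                      stage_cap_per_group=args.n_per_group,
                      roc_cap_per_stage=args.n_per_group)
    out = cmd_disease_study(cfg)

    fig, ax = plt.subplots(figsize=(5, 5))
    styles = {("early", "ri"): "-", ("early", "rbf"): "--",
              ("severe", "ri"): ":", ("severe", "rbf"): "-."}
    for key, r in out.roc.items():
        fpr = 1 - r.specificity
        order = fpr.argsort()
        ax.plot(fpr[order], r.sensitivity[order], styles.get(key, "-"),
                color="k", label=f"{key[0]}/{key[1].upper()} AUC={r.auc:.2f}")
        print(f"{key[0]}/{key[1]}: AUC={r.auc:.3f} cutoff={r.cutoff:.3g} "
              f"J={r.youden_j:.2f} ({r.orientation})")
    ax.plot([0, 1], [0, 1], color="grey", ls="--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    Path(args.outdir).mkdir(parents=True, exist_ok=True)
    fig.savefig(Path(args.outdir) / "roc_curves.png", dpi=150,
                bbox_inches="tight")
    print("Published reference: early-stage AUC 0.97 (RBF) vs 0.79 (RI); "
          "RBF separates diabetic from hypertensive nephropathy earlier.")


if __name__ == "__main__":
    main()
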