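"""Patient/control classification from regional AI + CFH features.

Features are the cluster means of every significant group-difference
region; a linear SVM (C = 1) is evaluated by leave-one-out cross-validation
with within-fold standardization, and the accuracy's significance comes
from a 1000-permutation label shuffle.  Writes results/classification.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hemilat.classification import FeatureMatrix, label_permutation_test, svm_loocv_classify
from hemilat.core_io import load_metric_map
from hemilat.group_inference import extract_cluster_mean
from hemilat.synthetic_cohort import load_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = load_cohort(ROOT / "cohort")
    geom = cohort.geometry
    pheno = cohort.phenotype
    cols, names = [], []
    for metric in ("ai", "cfh"):
        clusters = pd.read_csv(ROOT / "group" / f"{metric}_clusters.tsv", sep="\t")
        members = [np.array(m) for m in
                   json.load(open(ROOT / "group" / f"{metric}_cluster_members.json"))]
        maps = [
            load_metric_map(ROOT / "maps" / f"{sid}_{metric}.nii.gz", geom, metric.upper())
            for sid in pheno.subject_id
        ]
        for k, row in clusters.iterrows():
            if not row["significant"]:
                continue
            cols.append([extract_cluster_mean(m, members[k]) for m in maps])
            names.append(f"{metric}_{row['label']}")
    features = FeatureMatrix(np.array(cols).T, pheno.group.to_numpy(), names,
                             subject_ids=list(pheno.subject_id))
    report = svm_loocv_classify(features)
    report.permutation_p, _ = label_permutation_test(
        features, n_perm=1000, seed=42, observed_accuracy=report.accuracy
    )
    report.n_perm = 1000
    with open(ROOT / "classification.json", "w") as fh:
        fh.write(report.to_json(indent=1, sort_keys=True))
    print(f"features: {names}")
    print(f"accuracy    {report.accuracy:.1%}")
    print(f"sensitivity {report.sensitivity:.1%}")
    print(f"specificity {report.specificity:.1%}")
    print(f"AUC         {report.auc:.1%}")
    print(f"permutation p = {report.permutation_p:.4g} ({report.n_perm} permutations)")


if __name__ == "__main__":
    main()
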