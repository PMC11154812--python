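"""Imaging-cognition correlations, education-adjusted.

For every significant cluster, the cluster-mean metric value per patient
is correlated with MoCA and AVLT-immediate scores within the AD group,
partialling out years of education (which differs between groups by
construction, as in the emulated cohort).  Writes results/correlations.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hemilat.core_io import load_metric_map
from hemilat.group_inference import extract_cluster_mean, partial_correlation
from hemilat.synthetic_cohort import load_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"
SCORES = ("MoCA", "AVLT_I")


def main() -> None:
    cohort = load_cohort(ROOT / "cohort")
    geom = cohort.geometry
    pheno = cohort.phenotype
    ad = (pheno.group == "AD").to_numpy()
    education = pheno.loc[ad, "education"].to_numpy(float)
    rows = []
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
            values = np.array([extract_cluster_mean(m, members[k]) for m in maps])
            for score in SCORES:
                y = pheno.loc[ad, score].to_numpy(float)
                r, p = partial_correlation(values[ad], y, education)
                rows.append({"region": f"{metric}_{row['label']}", "score": score,
                             "r": round(r, 4), "p": round(p, 4), "n": int(ad.sum()),
                             "covariate": "education"})
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "correlations.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"written to {ROOT / 'correlations.tsv'}")


if __name__ == "__main__":
    main()
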