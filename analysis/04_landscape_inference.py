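"""Connectivity, category tests and regression-ready outputs.

Computes each pasture's landscape connectivity index, runs one-way
PERMANOVA of every total-dissimilarity matrix against pasture category,
and writes the per-category summary table together with
beta-regression-ready (epsilon-adjusted) OS' responses.
"""

from pathlib import Path

import pandas as pd

from netbeta import (
    PairwiseMatrix,
    category_summary,
    complete_case,
    complete_study,
    epsilon_adjust,
    metaweb_summary,
    network_size_metrics,
    pairwise_matrices,
    permanova,
    read_study,
    study_connectivity,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
N_PERM = 999
SEED = 1


def main():
    study = read_study(ROOT / "study" / "interactions.csv",
                       ROOT / "study" / "floral.csv",
                       ROOT / "study" / "sites.csv")
    study = complete_study(study)
    out = ROOT / "inference"
    out.mkdir(parents=True, exist_ok=True)
    labels = [s.category for s in study.sites]

    ci = study_connectivity(study)
    ci.to_csv(out / "connectivity.csv", index=False)
    print(f"connectivity: mean CI = {ci['CI'].mean():.3f} "
          f"(range {ci['CI'].min():.3f}-{ci['CI'].max():.3f})")

    rows = []
    mats_by_mode = {}
    for mode in ("quantitative", "binary"):
        mats = pairwise_matrices(study, mode)
        mats_by_mode[mode] = mats
        for comp in ("L", "U", "WN", "OS"):
            reduced, dropped = complete_case(mats[f"{comp}_total"])
            if dropped:
                print(f"  [{mode} {comp}] dropped {len(dropped)} site(s) with "
                      f"undefined entries: {dropped}")
            kept = [labels[study.site_ids.index(s)] for s in reduced.site_ids]
            res = permanova(reduced, kept, n_perm=N_PERM, seed=SEED)
            rows.append({"component": comp, "mode": mode, "pseudo_F": res["pseudo_F"],
                         "R2": res["R2"], "p": res["p_value"], "n_perm": N_PERM,
                         "seed": SEED, "n_sites_used": res["n_sites_used"]})
            print(f"[{mode}] PERMANOVA {comp}: F={res['pseudo_F']:.2f} "
                  f"R2={res['R2']:.3f} p={res['p_value']:.3f} (n={res['n_sites_used']})")
    pd.DataFrame(rows).to_csv(out / "permanova.csv", index=False)

    osp = metaweb_summary(study, "quantitative")
    per_site = osp[osp.site_id != "mean"].copy()
    per_site["total_adjusted"] = epsilon_adjust(per_site["total"].tolist())
    per_site.to_csv(out / "os_prime_regression_ready.csv", index=False)

    sizes = pd.DataFrame(
        [{"site_id": s.site_id, **network_size_metrics(s)} for s in study.sites])
    cat = category_summary(
        study,
        site_tables={"size": sizes, "ci": ci, "os_prime": per_site},
        matrices=mats_by_mode["quantitative"],
    )
    cat.to_csv(out / "category_summary.csv", index=False)
    print(f"inference tables written under {out}")


if __name__ == "__main__":
    main()
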