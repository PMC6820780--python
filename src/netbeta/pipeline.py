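"""End-to-end runner: study in, analysis tables out.

The run configuration is a YAML mapping with either a ``generator``
section (synthetic study) or an ``inputs`` section naming the three study
CSVs, plus optional ``exclude`` taxa, ``modes``, ``permanova`` and
``connectivity`` settings.  Outputs are written as CSVs under an output
directory together with a run log.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import inference, landscape, metaweb as mw_mod, network_beta, synthetic
from .beta_core import BINARY, QUANTITATIVE
from .io_model import (
    StudyData,
    ValidationError,
    complete_study,
    exclude_taxa,
    network_size_metrics,
    read_study,
    write_study,
)

log = logging.getLogger("netbeta")


class ConfigError(ValueError):
    """The run configuration is malformed."""


DEFAULT_CONFIG: dict = {
    "generator": {},
    "exclude": [],
    "modes": [QUANTITATIVE, BINARY],
    "permanova": {"n_perm": 999, "seed": 0, "component": "WN_total"},
    "connectivity": {"alpha": 1.0, "b": 0.5, "radius_km": 5.0},
}


def load_config(config_path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{config_path}: top level must be a mapping")
    for key in cfg:
        if key not in ("generator", "inputs", "exclude", "modes", "permanova", "connectivity", "seed"):
            raise ConfigError(f"{config_path}: unknown key {key!r}")
    merged = {k: v for k, v in DEFAULT_CONFIG.items()}
    merged.update({k: v for k, v in cfg.items() if k not in ("permanova", "connectivity")})
    for sect in ("permanova", "connectivity"):
        d = dict(DEFAULT_CONFIG[sect])
        d.update(cfg.get(sect) or {})
        merged[sect] = d
    if "inputs" in cfg and "generator" in cfg:
        raise ConfigError("config must name either 'inputs' or 'generator', not both")
    for m in merged["modes"]:
        if m not in (QUANTITATIVE, BINARY):
            raise ConfigError(f"unknown mode {m!r}")
    return merged


def _load_study(cfg: dict, seed: Optional[int]) -> StudyData:
    if "inputs" in cfg:
        inp = cfg["inputs"]
        for key in ("interactions", "floral", "sites"):
            if key not in inp:
                raise ConfigError(f"inputs section missing {key!r}")
        return read_study(inp["interactions"], inp["floral"], inp["sites"])
    gen = dict(cfg.get("generator") or {})
    if seed is not None:
        gen["seed"] = int(seed)
    gc = synthetic.GeneratorConfig.from_dict(gen)
    return synthetic.generate_study(gc)


def run_pipeline(config_path, outdir, seed: Optional[int] = None) -> dict:
    """Run the full analysis described by a YAML config; returns the
    in-memory result bundle (also written under ``outdir``)."""
    cfg = load_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, outdir, seed)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: dict, outdir: Path, seed: Optional[int]) -> dict:
    study = _load_study(cfg, seed)
    log.info("loaded study with %d sites", len(study.sites))
    if cfg["exclude"]:
        study = exclude_taxa(study, cfg["exclude"])
        log.info("excluded taxa: %s", sorted(cfg["exclude"]))
    study = complete_study(study)
    study.validate()
    write_study(study, outdir / "study")

    sizes = pd.DataFrame(
        [{"site_id": s.site_id, **network_size_metrics(s)} for s in study.sites]
    )
    sizes.to_csv(outdir / "network_sizes.csv", index=False)

    results: dict = {"study": study, "sizes": sizes}
    summaries = []
    matdir = outdir / "matrices"
    matdir.mkdir(exist_ok=True)
    perm_rows = []
    labels = [s.category for s in study.sites]

    for mode in cfg["modes"]:
        mats = network_beta.pairwise_matrices(study, mode)
        for key, m in mats.items():
            m.write_csv(matdir / f"{mode}_{key}.csv")
        summ = network_beta.summary_table(mats, mode)
        summaries.append(summ)
        results[f"matrices_{mode}"] = mats
        os_row = summ[summ.component == "OS"].iloc[0]
        if pd.notna(os_row["mean"]) and pd.notna(os_row["prop_turnover"]):
            rw = network_beta.rewiring_fraction(os_row["mean"], os_row["prop_turnover"])
        else:
            rw = float("nan")
        results[f"rewiring_fraction_{mode}"] = rw

        osp = mw_mod.metaweb_summary(study, mode)
        osp.to_csv(outdir / f"os_prime_{mode}.csv", index=False)
        results[f"os_prime_{mode}"] = osp

        # PERMANOVA on every component's total matrix
        pcfg = cfg["permanova"]
        for comp in network_beta.COMPONENTS:
            mat = mats[f"{comp}_total"]
            reduced, dropped = inference.complete_case(mat)
            for sid in dropped:
                log.info("PERMANOVA %s %s: dropped site %s (undefined entries)", mode, comp, sid)
            kept_labels = [labels[study.site_ids.index(s)] for s in reduced.site_ids]
            try:
                res = inference.permanova(
                    reduced, kept_labels, n_perm=int(pcfg["n_perm"]), seed=int(pcfg["seed"])
                )
            except (inference.DesignError, ValidationError) as err:
                log.warning("PERMANOVA %s %s skipped: %s", mode, comp, err)
                continue
            perm_rows.append(
                {
                    "component": comp,
                    "mode": mode,
                    "pseudo_F": res["pseudo_F"],
                    "R2": res["R2"],
                    "p": res["p_value"],
                    "n_perm": res["n_perm"],
                    "seed": int(pcfg["seed"]),
                    "n_sites_used": res["n_sites_used"],
                }
            )

    summary = pd.concat(summaries, ignore_index=True)
    summary["rewiring_fraction"] = [
        results[f"rewiring_fraction_{m}"] if c == "OS" else float("nan")
        for m, c in zip(summary["mode"], summary["component"])
    ]
    summary.to_csv(outdir / "summary.csv", index=False)
    results["summary"] = summary

    permanova_df = pd.DataFrame(perm_rows)
    permanova_df.to_csv(outdir / "permanova.csv", index=False)
    results["permanova"] = permanova_df

    mweb = mw_mod.build_metaweb(study)
    mw_mod.write_metaweb(mweb, outdir / "metaweb.csv")

    ccfg = cfg["connectivity"]
    ci = landscape.study_connectivity(
        study, alpha=ccfg["alpha"], b=ccfg["b"], radius_km=ccfg["radius_km"]
    )
    site_rows = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "category": s.category,
                "x_km": s.x_km,
                "y_km": s.y_km,
                "area_ha": s.area_ha,
                "years_since_restoration": s.years_since_restoration,
            }
            for s in study.sites
        ]
    ).merge(ci, on="site_id")
    site_rows.to_csv(outdir / "sites_with_ci.csv", index=False)
    results["sites_with_ci"] = site_rows

    cat_tables = {"size": sizes, "site": site_rows[["site_id", "CI"]]}
    for mode in cfg["modes"]:
        cat_tables[f"os_prime_{mode}"] = results[f"os_prime_{mode}"][
            results[f"os_prime_{mode}"]["site_id"] != "mean"
        ]
    first_mode = cfg["modes"][0]
    cat = inference.category_summary(
        study, site_tables=cat_tables, matrices=results[f"matrices_{first_mode}"]
    )
    cat.to_csv(outdir / "category_summary.csv", index=False)
    results["category_summary"] = cat

    log.info("pipeline complete: %d sites, modes %s", len(study.sites), cfg["modes"])
    return results
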