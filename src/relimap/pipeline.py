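"""End-to-end orchestration: one config in, one consolidated report out.

``run_all`` executes the reliability stages in a fixed order —
overlap -> voxel-wise ICC (+ atlas summary) -> similarity/fingerprinting
-> cross-condition correlation -> ratings — each only if its inputs are
configured, and collects every summary statistic together with the
settings that produced it into a versioned, machine-readable report.
Deterministic stages are bit-reproducible on identical inputs.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conditions as conditions_mod
from . import icc as icc_mod
from . import overlap as overlap_mod
from . import ratings as ratings_mod
from . import similarity as similarity_mod
from .io import load_atlas, load_ratings, load_stack, write_map

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def _schema() -> dict:
    with resources.files("relimap").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict) -> None:
    """Check a report against the bundled schema; raise ValueError on failure."""
    schema = _schema()
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    if report["schema_version"] != schema["schema_version"]:
        raise ValueError(
            f"schema version mismatch: report {report['schema_version']!r} "
            f"vs schema {schema['schema_version']!r}"
        )
    for section in schema["sections"]:
        if section not in report["sections"]:
            raise ValueError(f"report missing section {section!r}")
        body = report["sections"][section]
        if body.get("status") == "skipped":
            continue
        for key in schema["section_required_when_run"][section]:
            if key not in body:
                raise ValueError(f"section {section!r} missing key {key!r}")


def _parse_pairs(pairs) -> list[tuple[str, str]]:
    out = []
    for p in pairs:
        if isinstance(p, str):
            a, b = p.split(":")
        else:
            a, b = p
        out.append((a, b))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_all(config: dict, out_dir: str | Path, strict: bool = False) -> dict:
    """Run every configured stage and write report.json plus artifacts.

    Required config keys: manifest, mask, contrasts, session_pairs, and a
    threshold (df + p_threshold, or t_threshold). Optional: icc (contrast,
    sessions, cutoff, atlas, atlas_lut), similarity (contrast, pairs,
    method), conditions (food, neutral), ratings (path). Stages without
    configuration are marked "skipped" in the report. ``strict`` turns
    undefined-coefficient warnings into errors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "settings": _jsonable(
            {k: v for k, v in config.items() if not isinstance(v, (dict, list))}
            | {"config": config}
        ),
        "sections": {},
    }

    stack = load_stack(config["manifest"], config["mask"])
    pairs = _parse_pairs(config.get("session_pairs", []))
    contrasts = config.get("contrasts", list(stack.conditions))
    df = config.get("df")
    p_threshold = config.get("p_threshold", 0.001)
    t_threshold = config.get("t_threshold")

    # --- overlap ---------------------------------------------------------
    try:
        table = overlap_mod.overlap_table(
            stack, contrasts, pairs, df=df,
            p_threshold=p_threshold, t_threshold=t_threshold,
        )
    except Exception as exc:
        raise RuntimeError(f"stage overlap failed: {exc}") from exc
    n_undef = int(table["jaccard"].isna().sum())
    if strict and n_undef:
        raise RuntimeError(f"stage overlap: {n_undef} undefined coefficient(s)")
    summary = overlap_mod.overlap_summary(table)
    anova = None
    if len(contrasts) > 1 and len(pairs) > 1 and not n_undef:
        diff = next((c for c in contrasts if "minus" in c or ">" in c), None)
        anova = overlap_mod.rm_anova_overlap(table, "dice", difference_contrast=diff)
    table.to_csv(out_dir / "overlap_long.tsv", sep="\t", index=False)
    summary.to_csv(out_dir / "overlap_summary.tsv", sep="\t", index=False)
    report["sections"]["overlap"] = _jsonable(
        {
            "status": "run",
            "df": df,
            "p_threshold": p_threshold,
            "t_threshold": t_threshold,
            "n_undefined_pairs": n_undef,
            "table": table.to_dict(orient="records"),
            "summary": summary.to_dict(orient="records"),
            "anova": anova,
        }
    )

    # --- voxel-wise ICC --------------------------------------------------
    icc_cfg = config.get("icc")
    if icc_cfg:
        contrast = icc_cfg.get("contrast", contrasts[0])
        sessions = icc_cfg.get("sessions", list(stack.sessions))
        cutoff = icc_cfg.get("cutoff", 0.75)
        maps_out, means, above = {}, {}, {}
        subsets = [tuple(sessions)] + (
            [tuple(p) for p in pairs] if icc_cfg.get("pairs", "all") == "all" else []
        )
        for subset in dict.fromkeys(subsets):
            icc_map = icc_mod.voxelwise_icc(stack, contrast, list(subset))
            name = "icc_" + "_".join(subset)
            path = out_dir / f"{name}.nii.gz"
            write_map(icc_map.values, stack.mask, path)
            thr = icc_mod.threshold_icc(icc_map, cutoff)
            write_map(
                thr.active.astype(float), stack.mask,
                out_dir / f"{name}_gt{cutoff}.nii.gz",
            )
            key = ":".join(subset)
            maps_out[key] = path.name  # relative to the report directory
            means[key] = float(np.nanmean(icc_map.values))
            above[key] = int(thr.size)
            if len(subset) == len(sessions) and icc_cfg.get("atlas"):
                atlas = load_atlas(icc_cfg["atlas"], icc_cfg["atlas_lut"])
                roi = icc_mod.atlas_summary(icc_map, atlas)
                roi.to_csv(out_dir / "icc_atlas_summary.tsv", sep="\t", index=False)
                report.setdefault("extras", {})["atlas_summary"] = _jsonable(
                    roi.to_dict(orient="records")
                )
        report["sections"]["icc"] = _jsonable(
            {
                "status": "run",
                "contrast": contrast,
                "sessions": sessions,
                "cutoff": cutoff,
                "maps": maps_out,
                "mean_icc": means,
                "n_above_cutoff": above,
            }
        )
    else:
        report["sections"]["icc"] = {"status": "skipped"}

    # --- similarity / fingerprinting ------------------------------------
    sim_cfg = config.get("similarity")
    if sim_cfg:
        contrast = sim_cfg.get("contrast", contrasts[0])
        method = sim_cfg.get("method", "pearson")
        sim_pairs = _parse_pairs(sim_cfg.get("pairs", pairs))
        pair_reports = {}
        for sa, sb in sim_pairs:
            sim = similarity_mod.similarity_matrix(stack, contrast, sa, sb, method)
            fp = similarity_mod.reidentification(sim)
            t, tdf, p = similarity_mod.within_between_test(fp)
            pd.DataFrame(
                sim.values, index=sim.subjects, columns=sim.subjects
            ).to_csv(out_dir / f"similarity_{sa}_{sb}.tsv", sep="\t")
            ecdf = similarity_mod.similarity_ecdf(fp)
            for group, (v, f) in ecdf.items():
                pd.DataFrame({"value": v, "fraction": f}).to_csv(
                    out_dir / f"ecdf_{group}_{sa}_{sb}.tsv", sep="\t", index=False
                )
            pair_reports[f"{sa}:{sb}"] = {
                "rate": fp.rate,
                "n_scored": fp.n_scored,
                "n_identified": fp.n_identified,
                "mean_within_r": fp.mean_within,
                "mean_between_r": fp.mean_between,
                "welch_t": t,
                "welch_df": tdf,
                "p": p,
                "method": method,
            }
        report["sections"]["similarity"] = _jsonable(
            {"status": "run", "contrast": contrast, "pairs": pair_reports}
        )
    else:
        report["sections"]["similarity"] = {"status": "skipped"}

    # --- cross-condition correlation ------------------------------------
    cond_cfg = config.get("conditions")
    if cond_cfg:
        summary_df = conditions_mod.condition_correlation_summary(
            stack,
            cond_cfg["food"],
            cond_cfg["neutral"],
            cond_cfg.get("sessions"),
        )
        out = summary_df.drop(columns=["rho_per_subject"])
        out.to_csv(out_dir / "conditions.tsv", sep="\t", index=False)
        report["sections"]["conditions"] = _jsonable(
            {
                "status": "run",
                "pairs": out.to_dict(orient="records"),
            }
        )
    else:
        report["sections"]["conditions"] = {"status": "skipped"}

    # --- ratings ---------------------------------------------------------
    rat_cfg = config.get("ratings")
    if rat_cfg:
        table_r = load_ratings(rat_cfg["path"] if isinstance(rat_cfg, dict) else rat_cfg)
        matrix = ratings_mod.craving_contrast(table_r)
        icc_val, f, df1, df2, p = ratings_mod.ratings_icc(matrix)
        anova_r = ratings_mod.ratings_time_anova(matrix)
        report["sections"]["ratings"] = _jsonable(
            {
                "status": "run",
                "n_analyzed": int(matrix.shape[0]),
                "icc": {"icc": icc_val, "F": f, "df1": df1, "df2": df2, "p": p},
                "time_anova": anova_r,
            }
        )
    else:
        report["sections"]["ratings"] = {"status": "skipped"}

    validate_report(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
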