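"""End-to-end orchestration: screen -> diversity -> AMOVA -> clustering ->
P_ST-F_ST -> dispersal, driven by one config mapping.

Stages are isolated: a failure in one stage is recorded in the report and
later independent stages still run.  The global seed is propagated to every
stochastic stage with a fixed per-stage offset, so adding a stage never
perturbs earlier stages' random streams.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import McmcConfig, run_structure_analysis, structure_report
from .amova import format_amova_table, run_amova_suite
from .datamodel import AnalysisBundle, join_tables
from .dispersal import summarise_dispersal
from .diversity import screen_loci, summarise_loci, summary_frame
from .io import read_genepop, read_recaptures_csv, read_traits_csv
from .pst import pst_fst_compare, pst_sensitivity, trait_variance_components
from .simulate import SimulationConfig, make_study_fixture

STAGE_SEED_OFFSETS = {
    "screen": 100,
    "amova": 200,
    "admixture": 300,
    "pst": 400,
    "simulate": 500,
}


def validate_config(config: dict) -> list[str]:
    """Schema check; returns a list of violations (empty means ok)."""
    problems = []
    if "seed" not in config:
        problems.append("seed: missing (a global seed is mandatory)")
    has_inputs = "inputs" in config
    has_sim = "simulation" in config
    if has_inputs and has_sim:
        problems.append("inputs/simulation: exactly one of the two must be set")
    if not has_inputs and not has_sim:
        problems.append("inputs/simulation: one of the two must be set")
    if has_inputs and "genepop" not in config["inputs"]:
        problems.append("inputs.genepop: missing genotype file path")
    return problems


def validate_config_file(path) -> list[str]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        return ["config file must contain a mapping"]
    return validate_config(cfg)


def _load_bundle(config: dict) -> tuple[AnalysisBundle, list, dict]:
    seed = int(config["seed"])
    if "simulation" in config:
        sim = config["simulation"] or {}
        preset = sim.get("preset", "study")
        if preset != "study":
            raise ValueError(f"unknown simulation preset {preset!r}")
        overrides = {k: v for k, v in sim.items() if k != "preset"}
        sc = SimulationConfig(seed=seed + STAGE_SEED_OFFSETS["simulate"], **overrides)
        bundle, manifest = make_study_fixture(sc.seed, sc)
        return bundle, manifest.pop("recaptures"), manifest
    inputs = config["inputs"]
    table, meta = read_genepop(inputs["genepop"])
    traits = read_traits_csv(inputs["traits"]) if "traits" in inputs else None
    recaptures = (
        read_recaptures_csv(inputs["recaptures"]) if "recaptures" in inputs else []
    )
    return join_tables(table, meta, traits), recaptures, {}


def run_all(config: dict, output_dir=None) -> dict:
    """Run every stage and return the report mapping.

    Report sections: ``dispersal, screen, diversity, amova, structure,
    pst_fst`` plus ``provenance``.  A stage that raises is recorded as
    ``{"status": "failed", "error": ...}``.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    seed = int(config["seed"])
    report: dict = {
        "provenance": {
            "package": "valleypop",
            "version": __version__,
            "seed": seed,
            "config": _jsonable(config),
        }
    }

    bundle, recaptures, manifest = _load_bundle(config)
    if manifest:
        report["provenance"]["simulation_manifest"] = _jsonable(manifest)

    # --- dispersal ---------------------------------------------------
    try:
        if recaptures:
            ds = summarise_dispersal(recaptures)
            report["dispersal"] = {
                "status": "ok",
                "n_recaptured": ds.n_recaptured,
                "n_between_slope": ds.n_between_slope,
                "percent_between_slope": ds.percent_between_slope,
                "slope_matrix": ds.slope_matrix.to_dict(),
                "forest_matrix": ds.forest_matrix.to_dict(),
            }
        else:
            report["dispersal"] = {"status": "skipped", "reason": "no recapture records"}
    except Exception as exc:  # noqa: BLE001 - stage isolation
        report["dispersal"] = {"status": "failed", "error": str(exc)}

    # --- locus screen + diversity ------------------------------------
    screen_cfg = config.get("screen", {})
    retained_loci = list(bundle.genotypes.loci)
    try:
        summaries = summarise_loci(
            bundle.genotypes,
            n_mc=int(screen_cfg.get("n_mc", 2000)),
            seed=seed + STAGE_SEED_OFFSETS["screen"],
        )
        retained, discarded = screen_loci(
            summaries,
            hwe_alpha=float(screen_cfg.get("hwe_alpha", 0.05)),
            null_allele_max=float(screen_cfg.get("null_allele_max", 0.2)),
        )
        retained_loci = retained
        frame = summary_frame(summaries)
        report["screen"] = {
            "status": "ok",
            "note": "generic HWE/null-allele screen; thresholds configurable",
            "n_retained": len(retained),
            "n_discarded": len(discarded),
            "discarded": discarded,
        }
        report["diversity"] = {
            "status": "ok",
            "mean_k_alleles": float(frame["k_alleles"].mean()),
            "mean_h_obs": float(frame["h_obs"].mean()),
            "mean_h_exp": float(frame["h_exp"].mean()),
            "per_locus": frame.to_dict(orient="records"),
        }
    except Exception as exc:  # noqa: BLE001
        report["screen"] = {"status": "failed", "error": str(exc)}
        report["diversity"] = {"status": "failed", "error": str(exc)}

    # --- AMOVA -------------------------------------------------------
    amova_cfg = config.get("amova", {})
    f_st_global = None
    try:
        results = run_amova_suite(
            bundle,
            strata=tuple(amova_cfg.get("strata", ("all", "males", "females"))),
            n_permutations=int(amova_cfg.get("n_permutations", 10_000)),
            seed=seed + STAGE_SEED_OFFSETS["amova"],
            loci=retained_loci,
            permute=bool(amova_cfg.get("permute", True)),
        )
        section = {"status": "ok", "strata": {}}
        for name, res in results.items():
            if res is None:
                section["strata"][name] = {"status": "skipped"}
                continue
            section["strata"][name] = {
                "df": list(res.df),
                "sum_of_squares": list(res.ss),
                "variance_components": list(res.sigma2),
                "percent_variation": list(res.percent),
                "f_is": res.f_is,
                "f_st": res.f_st,
                "f_it": res.f_it,
                "f_is_mean_of_ratios": res.f_is_mean_of_ratios,
                "f_st_mean_of_ratios": res.f_st_mean_of_ratios,
                "f_it_mean_of_ratios": res.f_it_mean_of_ratios,
                "p_values": res.p_values,
            }
        f_st_global = results["all"].f_st if results.get("all") else None
        section["text_table"] = format_amova_table(results)
        report["amova"] = section
    except Exception as exc:  # noqa: BLE001
        report["amova"] = {"status": "failed", "error": str(exc)}

    # --- admixture clustering ----------------------------------------
    adm_cfg = config.get("admixture", {})
    try:
        mcmc = McmcConfig(
            iterations=int(adm_cfg.get("iterations", 20_000)),
            burn_in=int(adm_cfg.get("burn_in", 5_000)),
            thinning=int(adm_cfg.get("thinning", 10)),
            seed=seed + STAGE_SEED_OFFSETS["admixture"],
            frequency_model=adm_cfg.get("frequency_model", "correlated"),
        )
        analysis = run_structure_analysis(
            bundle.genotypes.subset_loci(retained_loci),
            k_range=range(int(adm_cfg.get("k_min", 1)), int(adm_cfg.get("k_max", 5)) + 1),
            replicates=int(adm_cfg.get("replicates", 5)),
            config=mcmc,
        )
        sel = analysis["selected_k"]
        rep = None
        if sel is not None and sel in analysis["mean_q"]:
            rep = structure_report(
                analysis["mean_q"][sel], bundle.genotypes.samples, bundle.metadata
            )
        report["structure"] = {
            "status": "ok",
            "note": "sampling-location prior (LOCPRIOR) not implemented",
            "selected_k": sel,
            "evanno": analysis["evanno"].to_dict(orient="records"),
            "population_means": (
                rep.attrs["population_means"].to_dict() if rep is not None else None
            ),
        }
    except Exception as exc:  # noqa: BLE001
        report["structure"] = {"status": "failed", "error": str(exc)}

    # --- P_ST vs F_ST ------------------------------------------------
    try:
        if bundle.traits is None or bundle.traits.empty:
            report["pst_fst"] = {"status": "skipped", "reason": "no trait table"}
        elif f_st_global is None:
            report["pst_fst"] = {"status": "failed", "error": "no AMOVA F_ST available"}
        else:
            section = {"status": "ok", "f_st": f_st_global, "traits": {}}
            meta = bundle.metadata.set_index("sample_id")
            for trait, sub in bundle.traits.groupby("trait"):
                labels = meta.loc[sub["sample_id"], "population"].to_numpy()
                comp = trait_variance_components(
                    sub["value"].to_numpy(), labels, trait=trait
                )
                res = pst_sensitivity(comp, f_st_global)
                section["traits"][trait] = _jsonable(pst_fst_compare(res))
            report["pst_fst"] = section
    except Exception as exc:  # noqa: BLE001
        report["pst_fst"] = {"status": "failed", "error": str(exc)}

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True)
        )
        (out / "report.md").write_text(render_markdown(report))
    return report


def render_markdown(report: dict) -> str:
    """Human-readable summary of a pipeline report."""
    lines = ["# valleypop analysis report", ""]
    d = report.get("dispersal", {})
    lines.append("## Natal dispersal")
    if d.get("status") == "ok":
        lines.append(
            f"- {d['n_recaptured']} recaptures; {d['n_between_slope']} between-slope "
            f"mover(s); {d['percent_between_slope']:.2f}% dispersal"
        )
    else:
        lines.append(f"- {d.get('status', 'missing')}")
    s = report.get("screen", {})
    lines += ["", "## Locus screen"]
    if s.get("status") == "ok":
        lines.append(f"- retained {s['n_retained']}, discarded {s['n_discarded']} "
                     f"({', '.join(s['discarded']) or 'none'})")
    dv = report.get("diversity", {})
    if dv.get("status") == "ok":
        lines += [
            "",
            "## Diversity",
            f"- mean alleles per locus {dv['mean_k_alleles']:.1f}; "
            f"mean H_O {dv['mean_h_obs']:.2f}; mean H_E {dv['mean_h_exp']:.2f}",
        ]
    a = report.get("amova", {})
    lines += ["", "## AMOVA"]
    if a.get("status") == "ok":
        lines.append("```")
        lines.append(a["text_table"])
        lines.append("```")
    st = report.get("structure", {})
    lines += ["", "## Bayesian clustering"]
    if st.get("status") == "ok":
        lines.append(f"- selected K (Delta-K): {st['selected_k']}")
    p = report.get("pst_fst", {})
    lines += ["", "## P_ST vs F_ST"]
    if p.get("status") == "ok":
        for trait, row in p["traits"].items():
            lines.append(
                f"- {trait}: P_ST(1,1) = {row['pst_null']:.3f} vs "
                f"F_ST = {row['f_st']:.3f} -> {row['classification']}"
            )
    else:
        lines.append(f"- {p.get('status', 'missing')}")
    return "\n".join(lines) + "\n"


def _jsonable(obj):
    """Recursively convert numpy / pandas values to plain JSON types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
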