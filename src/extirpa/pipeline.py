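"""Stage orchestration: simulate/ingest -> classify -> richness ->
community -> phylogenetic signal -> regression -> consolidated report.

The report is a plain nested dict (JSON-serializable) in which every number
is the direct output of one stage; provenance (config hash, seed, package
version) is attached at the top.  Stages degrade gracefully: without a tree
the phylogenetic stages are recorded as skipped, and a stage failure marks
the report and stops downstream stages rather than hiding the error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (axis_trend_regression, bray_curtis_matrix,
                        family_composition_test, filter_year_samples, ordinate,
                        period_rank_correlation)
from .pglm import backward_model_selection, collinearity_screen
from .records import (CodingRules, PeriodScheme, SpeciesFlags, parse_records,
                      summaries_to_frame, summarize_by_period)
from .richness import accumulation_curve, fit_cryptic_asymptote, ice_estimate
from .signal import BinaryTrait, d_statistic, ses_mpd
from .status import (StatusCategory, census, extinction_rate_report,
                     fisher_validate)
from .trees import Phylogeny
from . import synth

log = logging.getLogger("extirpa")

DEFAULT_PARAMS = {
    "min_abundant": 10,
    "rare_threshold": 10,
    "abundance_text_value": 10,
    "fixed_years": {},
    "old_period": [1923, 1943],
    "recent_period": [1993, 2013],
    "nmds_min_individuals": 300,
    "n_perm_d": 10000,
    "mpd_runs": 999,
    "btol": 1000.0,
    "ice_n_perm": 100,
    "accum_n_perm": 100,
    "resident_pool": None,  # default: the understory ICE estimate
}

__all__ = ["load_config", "run_pipeline", "DEFAULT_PARAMS"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            log.info("stage %s: %.2fs", name, dt)
            report.setdefault("timing_s", {})[name] = round(dt, 3)
            if exc is not None:
                log.error("stage %s failed: %s", name, exc)
                report["failed_stage"] = name
                report["failure"] = f"{exc_type.__name__}: {exc}"
            return True  # failure is recorded; downstream stages are skipped

    return _Ctx()


def run_pipeline(config: Mapping[str, Any], seed: int, out_dir: str | Path | None = None,
                 skip_stages: set[str] | None = None) -> dict:
    """Run all stages and return the consolidated report dict."""
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    skip = skip_stages or set()
    report: dict[str, Any] = {
        "provenance": {
            "config_hash": _config_hash(dict(config)),
            "seed": int(seed),
            "version": __version__,
            "schema": 1,
        }
    }
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(
                 ["simulate", "richness", "community", "phylo", "pglm"],
                 ss.spawn(5))}

    scheme = PeriodScheme(old=tuple(params["old_period"]),
                          recent=tuple(params["recent_period"]))
    rules = CodingRules(fixed_years=dict(params["fixed_years"]),
                        abundance_text_value=params["abundance_text_value"])

    # ---- ingest / simulate ----------------------------------------------
    tree = None
    traits = None
    truth = None
    cryptic_curve = None
    with _stage(report, "ingest"):
        if "simulate" in config:
            sim = dict(config["simulate"])
            n_species = int(sim.pop("n_species", 601))
            phylo_sigma = float(sim.pop("phylo_sigma", 0.5))
            n_cryptic = int(sim.pop("n_cryptic_total", 34))
            n_sequenced = int(sim.pop("n_sequenced", 1228))
            cfg = synth.CommunityConfig(n_species=n_species, **sim)
            tree = synth.simulate_phylogeny(n_species, seed=seeds["simulate"])
            traits = synth.simulate_trait_suite(tree, seed=seeds["simulate"] + 1)
            flags = synth.simulate_extinction(
                tree, traits, phylo_sigma=phylo_sigma, seed=seeds["simulate"] + 2)
            records_df, truth = synth.simulate_community_records(
                tree, flags, cfg, seed=seeds["simulate"] + 3)
            fam = synth.assign_families(tree)
            records_df = records_df.assign(
                family=records_df["species_id"].map(fam))
            cryptic_curve = synth.simulate_cryptic_accumulation(
                n_cryptic, n_sequenced, seed=seeds["simulate"] + 4)
            # only species that were recorded at least once (or carry a
            # status flag) enter the analysis; never-seen simulated species
            # have no real-world counterpart in a record compilation
            species_flags = {
                s: SpeciesFlags(
                    is_cryptic=truth.roles[s] == "cryptic",
                    described_after_1943=truth.roles[s] == "recently_described",
                    family=fam[s],
                )
                for s in truth.roles.index
                if truth.true_category[s] != 0
            }
            rules = CodingRules(fixed_years={"smallcoll": 1974},
                                abundance_text_value=params["abundance_text_value"])
        else:
            inputs = config["inputs"]
            records_df = pd.read_csv(inputs["records"])
            flags_df = (pd.read_csv(inputs["species_flags"], index_col=0)
                        if inputs.get("species_flags") else None)
            species_flags = {}
            if flags_df is not None:
                for s, row in flags_df.iterrows():
                    species_flags[str(s)] = SpeciesFlags(
                        is_cryptic=bool(row.get("is_cryptic", False)),
                        described_after_1943=bool(row.get("described_after_1943", False)),
                        family=row.get("family"),
                    )
            if inputs.get("tree"):
                tree = Phylogeny.from_newick(inputs["tree"])
            if inputs.get("traits"):
                traits = pd.read_csv(inputs["traits"], index_col=0)

        parsed = parse_records(records_df, rules)
        summaries = summarize_by_period(parsed.records, scheme, species_flags)
        report["ingest"] = {
            "n_records": len(parsed.records),
            "n_rejected": parsed.n_rejected,
            "n_species": len(summaries),
            "total_old": int(sum(s.n_old for s in summaries)),
            "total_recent": int(sum(s.n_recent for s in summaries)),
        }
        if out:
            summaries_to_frame(summaries).to_csv(out / "species_summaries.csv",
                                                 index=False)
            parsed.write_rejections(out / "rejected_rows.csv")
    if "failed_stage" in report:
        return _finalize(report, out)

    # ---- classify --------------------------------------------------------
    with _stage(report, "classify"):
        cen = census(summaries, min_abundant=params["min_abundant"])
        total_old = report["ingest"]["total_old"]
        total_recent = report["ingest"]["total_recent"]
        fishers = {}
        for sid in cen.species_in(StatusCategory.EXTINCT):
            s = next(x for x in summaries if x.species_id == sid)
            fr = fisher_validate(s.n_old, s.n_recent, total_old, total_recent)
            fishers[sid] = {"n_old": s.n_old, "n_recent": s.n_recent,
                            "p_two_sided": fr.p_two_sided}
        report["classify"] = {
            "census": {str(k): v for k, v in cen.counts.items()},
            "total": cen.total,
            "fisher_max_p": (max(f["p_two_sided"] for f in fishers.values())
                             if fishers else None),
            "fisher_all_below_1e4": (all(f["p_two_sided"] < 1e-4
                                         for f in fishers.values())
                                     if fishers else None),
        }
        if out:
            pd.DataFrame.from_dict(fishers, orient="index").to_csv(
                out / "fisher_validation.csv")
            pd.Series({s: int(c) for s, c in cen.assignments.items()},
                      name="category").to_csv(out / "categories.csv")
    if "failed_stage" in report:
        return _finalize(report, out)

    summary_frame = summaries_to_frame(summaries).set_index("species_id")

    # ---- richness --------------------------------------------------------
    with _stage(report, "richness"):
        if "richness" in skip:
            report["richness"] = {"skipped": True}
        else:
            per_year = {}
            for s in summaries:
                for y, c in s.per_year.items():
                    if scheme.classify_year(y) == "recent":
                        per_year.setdefault(y, {})[s.species_id] = c
            inc = pd.DataFrame(per_year).fillna(0)
            rich: dict[str, Any] = {}
            if inc.shape[1] >= 2:
                est = ice_estimate(inc, rare_threshold=params["rare_threshold"],
                                   n_perm=params["ice_n_perm"],
                                   seed=seeds["richness"])
                acc = accumulation_curve(inc, n_perm=params["accum_n_perm"],
                                         seed=seeds["richness"] + 1)
                rich.update({
                    "ice_recent": est.ice, "ice_recent_sd": est.sd,
                    "s_obs_recent": est.s_obs, "ice_fallback": est.fallback,
                    "n_units": inc.shape[1],
                })
                if out:
                    acc.as_frame().to_csv(out / "accumulation_recent.csv",
                                          index=False)
            if cryptic_curve is not None:
                x, y = cryptic_curve
                fit = fit_cryptic_asymptote(x, y)
                rich.update({"cryptic_discovered": int(y[-1]),
                             "cryptic_asymptote": fit.a,
                             "cryptic_fit_converged": fit.converged})
            report["richness"] = rich

    if "failed_stage" in report:
        return _finalize(report, out)

    # ---- rates -----------------------------------------------------------
    with _stage(report, "rates"):
        c = report["classify"]["census"]
        pool = params["resident_pool"]
        if pool is None:
            pool = report.get("richness", {}).get("ice_recent")
        if pool:
            report["rates"] = extinction_rate_report(
                n_extinct=c["9"], resident_pool=float(pool),
                n_unclear_not_recent=c["4"], n_total=report["classify"]["total"],
                n_common=c["7"], n_settler=c["8"],
            )
            report["rates"]["resident_pool"] = float(pool)
        else:
            report["rates"] = {"skipped": "no resident pool available"}

    if "failed_stage" in report:
        return _finalize(report, out)

    # ---- community -------------------------------------------------------
    with _stage(report, "community"):
        if "community" in skip:
            report["community"] = {"skipped": True}
        else:
            years = sorted({y for s in summaries for y in s.per_year})
            mat = pd.DataFrame(0, index=[s.species_id for s in summaries],
                               columns=years, dtype=float)
            for s in summaries:
                for y, cnt in s.per_year.items():
                    mat.loc[s.species_id, y] = cnt
            mat = filter_year_samples(mat, params["nmds_min_individuals"])
            comm: dict[str, Any] = {"n_year_samples": mat.shape[1]}
            if mat.shape[1] >= 4:
                bc = bray_curtis_matrix(mat.loc[(mat.sum(axis=1) > 0)])
                ordn = ordinate(bc, dims=2, seed=seeds["community"])
                effort = mat.sum(axis=0).to_numpy()
                yrs = np.array([float(c) for c in mat.columns])
                for axis in ("axis1", "axis2"):
                    reg = axis_trend_regression(
                        ordn.coordinates[axis].to_numpy(), yrs, effort)
                    comm[f"{axis}_F"] = reg.F
                    comm[f"{axis}_p"] = reg.p
                    comm[f"{axis}_r2"] = reg.r2
                comm["stress"] = ordn.stress
                if out:
                    ordn.coordinates.to_csv(out / "nmds_coordinates.csv")
            fam_col = summary_frame["family"].dropna()
            if fam_col.nunique() >= 2:
                tab = pd.DataFrame({
                    "old": summary_frame.loc[fam_col.index, "n_old"].groupby(fam_col).sum(),
                    "recent": summary_frame.loc[fam_col.index, "n_recent"].groupby(fam_col).sum(),
                })
                try:
                    ct = family_composition_test(tab)
                    comm["family_chi2"] = ct.chi2
                    comm["family_df"] = ct.df
                    comm["family_p"] = ct.p
                except ValueError as e:
                    comm["family_chi2_skipped"] = str(e)
            old_counts = summary_frame["n_old"]
            recent_counts = summary_frame["n_recent"]
            try:
                rho, n_inc, p = period_rank_correlation(old_counts, recent_counts)
                comm["period_spearman"] = rho
                comm["period_spearman_n"] = n_inc
                comm["period_spearman_p"] = p
            except ValueError as e:
                comm["period_spearman_skipped"] = str(e)
            report["community"] = comm

    if "failed_stage" in report:
        return _finalize(report, out)

    # ---- phylogenetic signal --------------------------------------------
    with _stage(report, "phylosig"):
        if tree is None or "phylosig" in skip:
            report["phylosig"] = {"skipped": True}
        else:
            extinct_ids = set(cen.species_in(StatusCategory.EXTINCT))
            tips = set(tree.tip_labels)
            trait = BinaryTrait.from_mapping(
                {t: int(t in extinct_ids) for t in tips})
            sig: dict[str, Any] = {}
            if 0 < trait.prevalence < 1 and len(extinct_ids & tips) >= 2:
                work = tree if tree.is_bifurcating else tree.resolve_polytomies(
                    seed=seeds["phylo"])
                dres = d_statistic(work, trait, n_perm=params["n_perm_d"],
                                   seed=seeds["phylo"])
                mres = ses_mpd(work, sorted(extinct_ids & tips),
                               n_runs=params["mpd_runs"], seed=seeds["phylo"] + 1)
                sig.update({
                    "d": dres.d, "sum_d_obs": dres.sum_d_obs,
                    "p_d_gt_0": dres.p_d_gt_0, "p_d_lt_1": dres.p_d_lt_1,
                    "mpd_obs": mres.mpd_obs, "mpd_null_mean": mres.null_mean,
                    "ses_mpd": mres.ses, "mpd_p": mres.p,
                })
            else:
                sig["skipped"] = "extinct trait degenerate on this tree"
            report["phylosig"] = sig

    if "failed_stage" in report:
        return _finalize(report, out)

    # ---- phylogenetic regression ----------------------------------------
    with _stage(report, "pglm"):
        if tree is None or traits is None or "pglm" in skip:
            report["pglm"] = {"skipped": True}
        else:
            cats = pd.Series({s: int(c) for s, c in cen.assignments.items()})
            keep = [s for s in cats.index
                    if cats[s] in (7, 8, 9) and s in set(tree.tip_labels)
                    and s in traits.index]
            pg: dict[str, Any] = {"n_species": len(keep)}
            if len(keep) >= 20 and cats.loc[keep].eq(9).sum() >= 3:
                from .pglm import build_design

                table = traits.loc[keep].copy()
                table["status"] = (cats.loc[keep] != 9).astype(int)
                design = build_design(table, "status",
                                      predictors=list(traits.columns))
                coll = collinearity_screen(design)
                sel = backward_model_selection(
                    tree.prune_to(keep), design, btol=params["btol"])
                fit = sel.selected
                pg.update({
                    "max_abs_spearman": coll.max_abs_rho,
                    "max_gvif": coll.max_gvif,
                    "alpha": fit.alpha,
                    "aicc": fit.aicc,
                    "selected_terms": sel.selected_design.terms,
                    "removed_terms": [r["dropped"] for r in sel.removal_log],
                    "coefficients": {k: float(v) for k, v in fit.beta.items()},
                    "p_values": {k: float(v) for k, v in fit.p.items()},
                    "converged": fit.converged,
                })
                if out:
                    fit.summary().to_csv(out / "pglm_selected.csv")
                    sel.aicc_table.to_csv(out / "pglm_aicc_table.csv", index=False)
            else:
                pg["skipped"] = "too few abundant-class species on the tree"
            report["pglm"] = pg

    return _finalize(report, out)


def _finalize(report: dict, out: Path | None) -> dict:
    def clean(obj):
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        return obj

    report = clean(report)
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
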