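"""End-to-end analysis pipeline.

Orchestrates the full sequence on a dataset (read from CSV or generated):
prevalence -> multiple imputation -> one-factor CFA (pooled) -> residual
network search -> Ising network with centrality -> measurement-invariance
ladder with partial-invariance search and group means -> structural
construct-validity model.  Writes CSV/JSON tables plus a log recording
seeds and all decision steps; re-running with the same seed reproduces
every table exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cfa, impute, invariance, networks, structural
from .data import AnalysisConfig, SMDS_ITEM_NAMES, summarize_prevalence
from .polychoric import estimate_summary
from .simulate import GeneratorSpec, default_spec, scale_map, simulate_dataset

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("smdsnet")


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _seed_for(config: AnalysisConfig, stage: str) -> int:
    """Deterministic per-stage substream below 2^31."""
    ss = np.random.SeedSequence([config.seed, abs(hash(stage)) % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: AnalysisConfig, spec: GeneratorSpec | None = None,
                 matrix=None, *, stages=None) -> dict:
    """Run the analysis and write its report bundle to ``config.out_dir``.

    ``matrix`` takes precedence over ``config.input_path``; with neither, a
    dataset is generated from ``spec`` (default: the emulated study
    conditions) at the configured seed.  ``stages`` optionally restricts
    the run (iterable of stage names).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {"config": asdict(config)}
    wanted = set(stages) if stages is not None else None

    def active(name):
        return wanted is None or name in wanted

    try:
        # ------------------------------------------------------------ data
        if matrix is None:
            if config.input_path:
                from .data import Codebook, read_responses

                matrix = read_responses(config.input_path, Codebook.smds())
                log.info("read %d rows from %s", matrix.n, config.input_path)
            else:
                spec = spec or default_spec()
                seed = _seed_for(config, "simulate")
                matrix = simulate_dataset(spec, seed)
                log.info("simulated dataset n=%d seed=%d", matrix.n, seed)
        spec = spec or default_spec()

        # ------------------------------------------------- prevalence
        if active("prevalence"):
            prev = summarize_prevalence(matrix, by_group=matrix.gender is not None,
                                        cutoff=config.cutoff)
            tab = prev.item_rates.rename("endorsement").to_frame()
            tab.loc["psmu_rate"] = prev.psmu_rate
            tab.to_csv(out / "prevalence.csv")
            results["prevalence"] = {"items": prev.item_rates.to_dict(),
                                     "psmu_rate": prev.psmu_rate,
                                     "n_complete": prev.n_complete}
            log.info("prevalence: psmu_rate=%.4f over %d complete rows",
                     prev.psmu_rate, prev.n_complete)

        # ------------------------------------------------- imputation
        ispec = impute.ImputationSpec(m=config.m_imputations,
                                      iterations=config.fcs_iterations,
                                      pmm_donors=config.pmm_donors,
                                      scale_of=scale_map(spec))
        seed = _seed_for(config, "impute")
        completed = impute.fcs_impute(matrix, ispec, seed)
        log.info("imputation: m=%d iterations=%d seed=%d", ispec.m,
                 ispec.iterations, seed)

        smds_completed = [c.select_items(SMDS_ITEM_NAMES) for c in completed]
        summaries = [estimate_summary(c.values, [2] * 9, list(SMDS_ITEM_NAMES))
                     for c in smds_completed]

        # ------------------------------------------------- CFA (pooled)
        if active("cfa"):
            est, var, fits = [], [], []
            for s in summaries:
                params, fitres, _ = cfa.fit_factor_model(s, ci_level=config.ci_level)
                est.append(np.concatenate([params.loadings,
                                           [t[0] for t in params.thresholds]]))
                var.append(np.concatenate([params.loadings_se,
                                           [t[0] for t in params.thresholds_se]]) ** 2)
                fits.append(fitres)
            pooled = impute.pool_rubin(np.array(est), np.array(var))
            ci = pooled.ci(config.ci_level)
            names = [f"loading_{nm}" for nm in SMDS_ITEM_NAMES] + \
                    [f"threshold_{nm}" for nm in SMDS_ITEM_NAMES]
            table = pd.DataFrame({"estimate": pooled.estimate,
                                  "se": np.sqrt(pooled.total),
                                  "lo": ci[:, 0], "hi": ci[:, 1]}, index=names)
            table.to_csv(out / "cfa_parameters.csv")
            fit_summary = {
                "t_scaled": float(np.mean([f.t_scaled for f in fits])),
                "df": fits[0].df,
                "sf": float(np.mean([f.sf for f in fits])),
                "cfi": float(np.mean([f.cfi for f in fits])),
                "rmsea": float(np.mean([f.rmsea for f in fits])),
                "srmr": float(np.mean([f.srmr for f in fits])),
                "spread_t": float(np.std([f.t_scaled for f in fits])),
            }
            (out / "cfa_fit.json").write_text(json.dumps(fit_summary, indent=2))
            rel = cfa.omega_reliability(pooled.estimate[:9],
                                        [np.array([t]) for t in pooled.estimate[9:]],
                                        "both")
            results["cfa"] = {"table": table, "fit": fit_summary,
                              "omega_latent": rel.omega_latent,
                              "omega_sumscore": rel.omega_sumscore}
            log.info("cfa: T=%.2f df=%d rmsea=%.4f", fit_summary["t_scaled"],
                     fit_summary["df"], fit_summary["rmsea"])

        # ------------------------------------------------- residual network
        if active("rnm"):
            fam = networks.RnmFamily(summaries[0])
            edges, trace, final = networks.stepwise_search(
                fam, initial_edges=[], alpha=config.edge_alpha)
            (out / "rnm_trace.json").write_text(
                json.dumps(trace.to_records(), default=float, indent=2))
            rnm_fits = [networks.fit_rnm(s, edges) for s in summaries]
            om = np.mean([f.omega for f in rnm_fits], axis=0)
            from .data import write_edge_list

            write_edge_list(out / "rnm_edges.tsv", list(SMDS_ITEM_NAMES), om,
                            se=rnm_fits[0].omega_se)
            results["rnm"] = {"edges": edges, "omega": om,
                              "fit": rnm_fits[0].fit, "trace": trace}
            log.info("rnm: %d edges retained (%d search steps)", len(edges),
                     len(trace.steps))

        # ------------------------------------------------- Ising network
        if active("ising"):
            X = smds_completed[0].values
            fam = networks.IsingFamily(X)
            full = frozenset(networks.all_pairs(9))
            edges_i, trace_i, model = networks.stepwise_search(
                fam, initial_edges=full, alpha=config.edge_alpha)
            cent = networks.centrality(model.weights, list(SMDS_ITEM_NAMES))
            cent.to_csv(out / "ising_centrality.csv")
            from .data import write_edge_list

            write_edge_list(out / "ising_edges.tsv", list(SMDS_ITEM_NAMES),
                            model.weights, se=model.weights_se)
            seed = _seed_for(config, "bootstrap")
            ranks, dropped = networks.bootstrap_centrality(
                X, edges_i, B=config.bootstrap_b, level=config.ci_level,
                seed=seed, node_names=list(SMDS_ITEM_NAMES))
            for ix, df in ranks.items():
                df.to_csv(out / f"ising_rank_ci_{ix}.csv")
            results["ising"] = {"edges": edges_i, "model": model,
                                "centrality": cent, "rank_ci": ranks,
                                "bootstrap_dropped": dropped}
            log.info("ising: %d edges, bootstrap B=%d seed=%d (%d dropped)",
                     len(edges_i), config.bootstrap_b, seed, dropped)

        # ------------------------------------------------- invariance
        if active("invariance") and matrix.gender is not None:
            smds1 = smds_completed[0]
            smds1.gender, smds1.age = matrix.gender, matrix.age
            crit = invariance.InvarianceCriteria(
                metric_rmsea=config.metric_delta_rmsea,
                scalar_rmsea=config.scalar_delta_rmsea, cfi=config.delta_cfi)
            inv_results = {}
            for by in (("gender",), ("age_class",)):
                labels, summ, ns = invariance.group_summaries(smds1, by)
                conf = invariance.fit_multigroup(summ, ns, "configural",
                                                 labels=labels)
                met = invariance.fit_multigroup(summ, ns, "metric",
                                                labels=labels)
                rows = [_fit_row("configural", conf, None),
                        _fit_row("metric", met,
                                 invariance.compare_levels(conf, met, "metric", crit))]
                sca = invariance.fit_multigroup(summ, ns, "scalar", labels=labels)
                comp = invariance.compare_levels(met, sca, "scalar", crit)
                rows.append(_fit_row("scalar", sca, comp))
                final = sca
                if comp.verdict == "reject":
                    ps = invariance.partial_invariance_search(
                        summ, ns, met, "scalar", labels=labels, criteria=crit)
                    final = ps.fit
                    rows.append(_fit_row("partial_scalar", ps.fit,
                                         ps.comparisons[-1]))
                    log.info("invariance %s: freed %s", by,
                             sorted(ps.freed.keys()))
                lmi = invariance.fit_multigroup(summ, ns, "latent_means",
                                                freed=final.freed or None,
                                                labels=labels)
                rows.append(_fit_row("latent_means", lmi,
                                     invariance.compare_levels(final, lmi,
                                                               "latent_means",
                                                               crit)))
                means = invariance.estimate_group_means(final,
                                                        ci_level=config.ci_level)
                key = "_".join(by)
                pd.DataFrame(rows).to_csv(out / f"invariance_{key}.csv",
                                          index=False)
                means.table.to_csv(out / f"group_means_{key}.csv")
                inv_results[key] = {"ladder": rows, "means": means}
            results["invariance"] = inv_results

        # ------------------------------------------------- structural model
        if active("structural") and spec.aux_blocks and \
                len(matrix.items) > 9:
            est, var = [], []
            names = None
            for c in completed:
                s = estimate_summary(c.values, c.n_categories, c.item_names)
                blocks = structural.BlockSpec.from_counts(
                    ["smds"] + [b.name for b in spec.aux_blocks],
                    [9] + [b.n_items for b in spec.aux_blocks])
                res = structural.fit_structural(s, blocks,
                                                ci_level=config.ci_level)
                tab = res.table()
                names = list(zip(tab["construct_a"], tab["construct_b"]))
                est.append(tab["r"].to_numpy())
                var.append(tab["se"].to_numpy() ** 2)
            pooled = impute.pool_rubin(np.array(est), np.array(var))
            ci = pooled.ci(config.ci_level)
            tab = pd.DataFrame({"construct_a": [a for a, _ in names],
                                "construct_b": [b for _, b in names],
                                "r": pooled.estimate,
                                "se": np.sqrt(pooled.total),
                                "lo": ci[:, 0], "hi": ci[:, 1]})
            tab.to_csv(out / "structural_correlations.csv", index=False)
            results["structural"] = {"table": tab}
            log.info("structural: %d latent correlations pooled over m=%d",
                     len(tab), config.m_imputations)

    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineError(_current_stage(results), e) from e
    finally:
        log.removeHandler(handler)
        handler.close()

    return results


def _current_stage(results: dict) -> str:
    order = ["prevalence", "cfa", "rnm", "ising", "invariance", "structural"]
    done = [k for k in order if k in results]
    idx = len(done)
    return order[idx] if idx < len(order) else "output"


def _fit_row(level, fit, comp) -> dict:
    row = {"model": level, "chi2": fit.fit.t_scaled, "df": fit.fit.df,
           "sf": fit.fit.sf, "cfi": fit.fit.cfi, "rmsea": fit.fit.rmsea,
           "rmsea_lo": fit.fit.rmsea_ci90[0], "rmsea_hi": fit.fit.rmsea_ci90[1],
           "srmr": fit.fit.srmr}
    if comp is not None:
        row.update({"d_chi2": comp.d_chi2, "d_df": comp.d_df,
                    "d_cfi": comp.d_cfi, "d_rmsea": comp.d_rmsea,
                    "d_srmr": comp.d_srmr, "decision": comp.verdict})
    return row
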