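"""End-to-end orchestration: cohort -> QC -> connectomes -> consensus ->
metrics -> subnetworks -> group inference -> NBS.

Each stage writes its table under the output directory; a manifest
records package version, seeds, thresholds and a digest of the full
configuration for provenance. Any stage failure aborts with the stage
name while earlier outputs are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import ocsnet
from ocsnet import qc as qc_mod
from ocsnet.cohort import CohortSpec, GroupEffect, SyntheticSubject, generate_cohort, planted_layout
from ocsnet.community import Partition, consensus_partition
from ocsnet.connectome import ConnectivityMatrix, build_connectivity, write_matrix
from ocsnet.metrics import (
    ThalamicNodeSet,
    global_metrics,
    participation_coefficients,
    thalamic_summary,
    within_module_z,
)
from ocsnet.phenotype import RegressionResult, apply_fdr, fit_model, impute_ethnicity
from ocsnet.subnetwork import between_subnetwork_means, subnetwork_table
from ocsnet.nbs import NBSConfig, nbs_test

log = logging.getLogger("ocsnet")

__all__ = ["PipelineConfig", "run_pipeline", "regress_families", "metrics_tables"]


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str
    cohort: CohortSpec
    gamma: float = 1.05
    consensus_reps: int = 50
    consensus_tau: float = 0.5
    consensus_mode: str = "pooled"
    mean_fd_thresh: float = 0.25
    spike_fd_thresh: float = 0.2
    spike_frac: float = 0.20
    apply_denoise: bool = False
    n_boot: int = 10_000
    n_perm: int = 5000
    nbs_threshold: float = 3.0
    model: int = 1
    n_rand_sigma: int = 10
    subject_louvain: bool = False
    predictors: tuple[str, ...] = ("socs_sum", "probable_ocd", "high_ocs")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohort_raw = raw.pop("cohort")
        effect = cohort_raw.pop("effect", None)
        if effect is not None:
            pair = effect.pop("pair", None)
            effect = GroupEffect(pair=tuple(pair) if pair else None, **effect)
        spec = CohortSpec(effect=effect, **cohort_raw)
        preds = raw.pop("predictors", None)
        cfg = cls(cohort=spec, **raw)
        if preds is not None:
            cfg = PipelineConfig(**{**cfg.__dict__, "predictors": tuple(preds)})
        return cfg


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def metrics_tables(
    matrices: dict[str, ConnectivityMatrix],
    partition: Partition,
    node_set: ThalamicNodeSet | None,
    gamma: float = 1.05,
    n_rand: int = 10,
    seed: int = 0,
    subject_louvain: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject global metrics table and subnetwork-pair table.

    By default modularity is evaluated against the shared (consensus)
    partition so Q is comparable across subjects; ``subject_louvain``
    instead optimizes a partition per subject for Q. Nodal and subnetwork
    measures always use the shared partition.
    """
    from ocsnet.community import louvain_partition
    from ocsnet.metrics import modularity

    rng = np.random.default_rng(seed)
    rows = []
    subnet: dict[str, object] = {}
    for sid, w in matrices.items():
        gm = global_metrics(w, partition, gamma=gamma, n_rand=n_rand, seed=int(rng.integers(2**31)))
        q = gm.Q
        if subject_louvain:
            own = louvain_partition(w, gamma=gamma, seed=int(rng.integers(2**31)))
            q = modularity(w, own, gamma=gamma)
        row = {
            "subject_id": sid,
            "avg_pc": gm.avg_pc,
            "Q": q,
            "sigma": gm.sigma,
            "C": gm.C,
            "L": gm.L,
            "E_glob": gm.E_glob,
        }
        if node_set is not None:
            pc = dict(zip(w.node_labels, participation_coefficients(w, partition)))
            z = dict(zip(w.node_labels, within_module_z(w, partition)))
            for name, v in thalamic_summary(pc, node_set, partition).items():
                row[f"pc_{name}"] = v
            for name, v in thalamic_summary(z, node_set, partition).items():
                row[f"z_{name}"] = v
        rows.append(row)
        subnet[sid] = between_subnetwork_means(w, partition)
    return pd.DataFrame(rows), subnetwork_table(subnet)


def _predictor_frame(pheno: pd.DataFrame, predictor: str) -> pd.DataFrame:
    """Subset subjects and build the predictor column for one contrast.

    socs_sum: all scored subjects, continuous. probable_ocd: cases vs
    symptom-free controls only (0 < SOCS < 6 subjects dropped). high_ocs:
    any item 'often' vs everyone with all items <= 1.
    """
    df = pheno[~pheno["excluded_missing_socs"].astype(bool)].copy()
    if predictor == "socs_sum":
        df["x"] = df["socs_sum"].astype(float)
    elif predictor == "probable_ocd":
        df = df[df["probable_ocd"].astype(bool) | df["control"].astype(bool)]
        df["x"] = df["probable_ocd"].astype(float)
    elif predictor == "high_ocs":
        df["x"] = df["high_ocs"].astype(float)
    else:
        raise ValueError(f"unknown predictor: {predictor}")
    return df


def regress_families(
    metrics_df: pd.DataFrame,
    subnet_df: pd.DataFrame,
    pheno: pd.DataFrame,
    predictor: str = "socs_sum",
    model: int = 1,
    n_boot: int = 10_000,
    seed: int = 0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted models at all three scales, FDR within families.

    Families: global (avg_pc, Q, sigma; no FDR, matching the three
    preregistered global tests), subnetwork (the 10 between-community
    means, BH-FDR), thalamic PC and thalamic Z (9 node values each,
    BH-FDR). Model 1 adjusts for age, sex, ethnicity; model 2 adds the
    adjusted CBCL score.
    """
    pheno = pheno.copy()
    eth = pheno["ethnicity"].replace("", np.nan)
    pheno["ethnicity"] = impute_ethnicity(eth, seed=seed)
    df = _predictor_frame(pheno, predictor)

    wide = subnet_df[~subnet_df["within"]].copy()
    wide["pair"] = "between_" + wide["community_a"].astype(str) + "_" + wide["community_b"].astype(str)
    wide = wide.pivot(index="subject_id", columns="pair", values="mean_connectivity").reset_index()
    data = df.merge(metrics_df, on="subject_id").merge(wide, on="subject_id")

    cov_cols = ["age", "sex", "ethnicity"] + (["cbcl_adj"] if model == 2 else [])
    covariates = data[cov_cols]
    rng = np.random.default_rng(seed)

    def fit(col: str) -> RegressionResult:
        return fit_model(
            data[col].to_numpy(float),
            data["x"].to_numpy(float),
            covariates,
            n_boot=n_boot,
            seed=int(rng.integers(2**31)),
            outcome_name=col,
        )

    families: dict[str, list[RegressionResult]] = {
        "global": [fit(c) for c in ("avg_pc", "Q", "sigma")],
        "subnetwork": [fit(c) for c in wide.columns if c != "subject_id"],
        "thalamic_pc": [fit(c) for c in metrics_df.columns if c.startswith("pc_")],
        "thalamic_z": [fit(c) for c in metrics_df.columns if c.startswith("z_")],
    }
    rows = []
    for fam, results in families.items():
        if fam != "global" and results:
            results = apply_fdr(results, q=q)
        for r in results:
            rows.append(
                {
                    "family": fam,
                    "predictor": predictor,
                    "model": model,
                    "outcome": r.outcome_name,
                    "n": r.n,
                    "B": r.B,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "beta": r.beta_std,
                    "t": r.t,
                    "p": r.p,
                    "fdr_significant": r.p_fdr_significant,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns a bundle of in-memory results.

    Writes qc_report.tsv, matrices/, consensus_partition.tsv, metrics.tsv,
    subnetworks.tsv, regression_results.tsv, nbs_results.tsv and
    manifest.json under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        subjects = generate_cohort(config.cohort)
        _, node_set = planted_layout(
            config.cohort.n_nodes, config.cohort.n_communities, config.cohort.thalamic_pairs
        )
        pheno = _phenotype_frame(subjects)
        pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)

        stage = "qc"
        qc_rows = []
        included: list[SyntheticSubject] = []
        for s in subjects:
            rep = qc_mod.motion_exclude(
                s.fd_trace, config.mean_fd_thresh, config.spike_fd_thresh, config.spike_frac
            )
            reasons = list(rep.reasons)
            if s.phenotype.excluded_missing_socs:
                reasons.append("missing_socs")
            qc_rows.append(
                {"subject_id": s.subject_id, "included": not reasons, "reasons": ";".join(reasons)}
            )
            if not reasons:
                included.append(s)
        pd.DataFrame(qc_rows).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        if not included:
            raise ValueError("QC excluded every subject")
        dropped = set()
        for s in included:
            dropped.update(qc_mod.drop_zero_variance_nodes(s.timeseries))
        keep = [l for l in included[0].timeseries.node_labels if l not in dropped]

        stage = "connectivity"
        matrices: dict[str, ConnectivityMatrix] = {}
        (out / "matrices").mkdir(exist_ok=True)
        for s in included:
            ts = s.timeseries.select_nodes(keep) if dropped else s.timeseries
            if config.apply_denoise:
                ts = qc_mod.denoise(ts)
            m = build_connectivity(ts)
            matrices[s.subject_id] = m
            write_matrix(m, out / "matrices" / f"{s.subject_id}.tsv")

        stage = "consensus"
        cons = consensus_partition(
            list(matrices.values()),
            gamma=config.gamma,
            n_reps=config.consensus_reps,
            tau=config.consensus_tau,
            seed=config.seed,
            mode=config.consensus_mode,
        )
        partition = cons.partition
        pd.DataFrame(
            {"node_label": partition.node_labels, "community": partition.membership}
        ).to_csv(out / "consensus_partition.tsv", sep="\t", index=False)
        np.savetxt(out / "coassignment.tsv", cons.coassignment, fmt="%.4g", delimiter="\t")

        stage = "metrics"
        if node_set is not None and dropped:
            node_set = None  # thalamic pairs incomplete after node drops
        metrics_df, subnet_df = metrics_tables(
            matrices, partition, node_set,
            gamma=config.gamma, n_rand=config.n_rand_sigma, seed=config.seed,
            subject_louvain=config.subject_louvain,
        )
        metrics_df.to_csv(out / "metrics.tsv", sep="\t", index=False)
        subnet_df.to_csv(out / "subnetworks.tsv", sep="\t", index=False)

        stage = "regress"
        pheno_inc = pheno[pheno["subject_id"].isin(matrices.keys())].reset_index(drop=True)
        results = pd.concat(
            [
                regress_families(
                    metrics_df, subnet_df, pheno_inc,
                    predictor=pred, model=config.model,
                    n_boot=config.n_boot, seed=config.seed,
                )
                for pred in config.predictors
            ],
            ignore_index=True,
        )
        results.to_csv(out / "regression_results.tsv", sep="\t", index=False)

        stage = "nbs"
        nbs_df = _nbs_stage(matrices, pheno_inc, config)
        nbs_df.to_csv(out / "nbs_results.tsv", sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "ocsnet_version": ocsnet.__version__,
            "seed": config.seed,
            "gamma": config.gamma,
            "consensus": {
                "reps": config.consensus_reps,
                "tau": config.consensus_tau,
                "mode": config.consensus_mode,
                "iterations": cons.iterations,
                "converged": cons.converged,
                "K": partition.K,
            },
            "qc": {
                "mean_fd_thresh": config.mean_fd_thresh,
                "spike_fd_thresh": config.spike_fd_thresh,
                "spike_frac": config.spike_frac,
                "n_included": len(included),
                "n_dropped_nodes": len(dropped),
            },
            "n_boot": config.n_boot,
            "n_perm": config.n_perm,
            "nbs_threshold": config.nbs_threshold,
            "config_digest": _digest(config.__dict__),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return {
        "phenotypes": pheno,
        "qc": pd.DataFrame(qc_rows),
        "matrices": matrices,
        "consensus": cons,
        "metrics": metrics_df,
        "subnetworks": subnet_df,
        "regression": results,
        "nbs": nbs_df,
        "manifest": manifest,
    }


def _phenotype_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rec = s.phenotype
        rows.append(
            {
                "subject_id": rec.subject_id,
                **{f"socs_item_{i+1}": rec.socs_items[i] for i in range(7)},
                "socs_sum": rec.socs_sum,
                **rec.groups,
                "age": rec.age,
                "sex": rec.sex,
                "ethnicity": rec.ethnicity if rec.ethnicity is not None else "",
                "cbcl_adj": rec.cbcl_adj,
            }
        )
    return pd.DataFrame(rows)


def _nbs_stage(
    matrices: dict[str, ConnectivityMatrix], pheno: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Probable-OCD vs symptom-free-control NBS contrast, both directions."""
    df = pheno[pheno["probable_ocd"].astype(bool) | pheno["control"].astype(bool)]
    rows = []
    if df["probable_ocd"].astype(bool).sum() < 2 or df["control"].astype(bool).sum() < 2:
        log.warning("NBS skipped: fewer than 2 subjects in a contrast group")
        return pd.DataFrame(columns=["direction", "component_id", "size", "p_fwer"])
    mats = [matrices[sid] for sid in df["subject_id"]]
    groups = df["probable_ocd"].astype(float).to_numpy()
    for direction in ("greater", "less"):
        res = nbs_test(
            mats,
            groups,
            config=NBSConfig(
                primary_threshold=config.nbs_threshold,
                n_perm=config.n_perm,
                seed=config.seed,
                direction=direction,
            ),
        )
        for i, comp in enumerate(res.components):
            rows.append(
                {"direction": direction, "component_id": i, "size": comp.size, "p_fwer": comp.p_fwer}
            )
    return pd.DataFrame(rows, columns=["direction", "component_id", "size", "p_fwer"])
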