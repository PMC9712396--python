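"""Synthetic cohort generator emulating the study's data structure.

Each subject gets a T x N regional timeseries with planted community
structure, a 7-item SOCS phenotype with configurable case-group
prevalences, model covariates, and a framewise-displacement trace. The
timeseries come from a latent-factor model: every community has a
unit-variance AR(1) latent signal; latents of different communities are
correlated at ``between_coupling / within_coupling`` so that, before
noise, the expected Pearson correlation is ``within_coupling`` inside a
community and ``between_coupling`` across communities (optionally
pair-specific). i.i.d. Gaussian noise with SD ``noise_sd`` is added per
node. Group effects are planted generatively: reducing a community pair's
between-coupling for one symptom group, or reducing all between-couplings
(a modularity shift).

Sixteen nodes form eight bilateral "thalamic" pairs tagged with the
thalamic subregion names; seven pairs live in one community each, the
caudal temporal pair is split across two communities, mirroring the
study's 9-value nodal analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ocsnet.community import Partition
from ocsnet.connectome import Timeseries
from ocsnet.metrics import ThalamicNodeSet
from ocsnet.phenotype import PhenotypeRecord, classify_groups

__all__ = [
    "GroupEffect",
    "CohortSpec",
    "SyntheticSubject",
    "generate_timeseries",
    "generate_phenotypes",
    "generate_cohort",
    "planted_layout",
    "write_cohort",
]

#: Thalamic subregions of the Brainnetome parcellation used for node tags.
THALAMIC_SUBREGIONS = (
    "mPFtha",  # medial prefrontal
    "mPMtha",  # premotor
    "Stha",    # sensory
    "rTtha",   # rostral temporal
    "PPtha",   # posterior parietal
    "Otha",    # occipital
    "cTtha",   # caudal temporal (the split pair)
    "lPFtha",  # lateral prefrontal
)
SPLIT_SUBREGION = "cTtha"

_AR_PHI = 0.3  # latent AR(1) coefficient


@dataclass(frozen=True)
class GroupEffect:
    """Planted generative group difference.

    target: 'between_coupling_pair' reduces one community pair's coupling;
    'modularity_shift' reduces every between-community coupling (raising
    modularity) for the affected group.
    """

    target: str
    magnitude: float
    affected_group: str
    pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.target not in ("between_coupling_pair", "modularity_shift"):
            raise ValueError(f"unknown effect target: {self.target}")
        if self.affected_group not in ("probable_ocd", "high_ocs"):
            raise ValueError(f"unknown affected group: {self.affected_group}")
        if self.target == "between_coupling_pair" and self.pair is None:
            raise ValueError("between_coupling_pair effect needs a community pair")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_subjects: int
    n_nodes: int = 60
    n_communities: int = 5
    timeseries_length: int = 196  # 200 volumes minus 4 non-steady-state
    within_coupling: float = 0.5
    between_coupling: float = 0.1
    noise_sd: float = 0.8
    effect: GroupEffect | None = None
    prevalence: dict = field(
        default_factory=lambda: {"probable_ocd": 0.064, "high_ocs": 0.078}
    )
    missing_item_rate: float = 0.02
    thalamic_pairs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.n_communities > self.n_nodes:
            raise ValueError("more communities than nodes")
        if not (0 <= self.between_coupling <= self.within_coupling <= 1):
            raise ValueError("need 0 <= between_coupling <= within_coupling <= 1")
        if self.timeseries_length < 20:
            raise ValueError("timeseries_length must be >= 20")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive (degenerate correlations otherwise)")
        for g, p in self.prevalence.items():
            if not (0 <= p < 1):
                raise ValueError(f"prevalence for {g} outside [0, 1)")
        if sum(self.prevalence.values()) >= 1:
            raise ValueError("prevalence fractions must jointly be < 1")
        if self.thalamic_pairs and self.n_nodes < 2 * len(THALAMIC_SUBREGIONS) + self.n_communities:
            raise ValueError("too few nodes to place 8 bilateral thalamic pairs")
        if self.effect is not None:
            between = self.effect.magnitude
            if self.between_coupling - between < 0:
                raise ValueError("effect magnitude would make a coupling negative")


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    timeseries: Timeseries
    phenotype: PhenotypeRecord
    planted_partition: Partition
    fd_trace: np.ndarray


def planted_layout(
    n_nodes: int, n_communities: int, thalamic: bool = True
) -> tuple[Partition, ThalamicNodeSet | None]:
    """Node labels, planted partition and thalamic pair placement.

    Communities are near-equal-sized. When ``thalamic`` is set, the last 16
    nodes are relabeled as 8 bilateral subregion pairs; each pair is placed
    inside one community except the caudal temporal pair, whose left node
    goes to community 0 and right node to community 1.
    """
    K = n_communities
    quota = [n_nodes // K + (1 if c < n_nodes % K else 0) for c in range(K)]
    thal_labels: list[str] = []
    thal_membership: list[int] = []
    node_set = None
    if thalamic:
        pairs = []
        for k, sub in enumerate(THALAMIC_SUBREGIONS):
            left, right = f"{sub}_L", f"{sub}_R"
            if sub == SPLIT_SUBREGION:
                cl, cr = 0, 1 % K
            else:
                cl = cr = k % K
            thal_labels += [left, right]
            thal_membership += [cl, cr]
            pairs.append((sub, left, right))
        node_set = ThalamicNodeSet(tuple(pairs))
    # generic nodes top communities up to their quota, keeping sizes balanced
    counts = np.bincount(thal_membership, minlength=K) if thal_membership else np.zeros(K, int)
    if np.any(counts > quota):
        raise ValueError("community quotas too small for the thalamic pair placement")
    labels = [f"node_{i:03d}" for i in range(n_nodes - len(thal_labels))]
    generic_membership = np.repeat(np.arange(K), np.asarray(quota) - counts)
    membership = np.concatenate([generic_membership, thal_membership]).astype(int)
    part = Partition(tuple(labels + thal_labels), membership).canonicalized()
    return part, node_set


def _latent_correlation(
    K: int, within: float, between: np.ndarray | float
) -> np.ndarray:
    """K x K latent correlation matrix implementing the coupling targets."""
    B = np.full((K, K), float(between)) if np.isscalar(between) else np.asarray(between, dtype=float)
    if np.any(B < 0):
        raise ValueError("between-community couplings must be non-negative")
    if np.any(B > within + 1e-12):
        raise ValueError("between_coupling cannot exceed within_coupling")
    if within == 0:
        return np.eye(K)
    C = B / within
    np.fill_diagonal(C, 1.0)
    if np.linalg.eigvalsh(C).min() < -1e-9:
        raise ValueError("coupling targets yield a non-PSD latent correlation")
    return C


def _correlated_ar1(T: int, C: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """T x K unit-variance AR(1) latents with cross-correlation C."""
    K = C.shape[0]
    eps = rng.standard_normal((T, K))
    u = np.empty((T, K))
    u[0] = eps[0]
    scale = math.sqrt(1 - _AR_PHI**2)
    for t in range(1, T):
        u[t] = _AR_PHI * u[t - 1] + scale * eps[t]
    # mix stationary AR(1) series; same phi for all, so cross-corr is exactly C
    vals, vecs = np.linalg.eigh(C)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None))) @ vecs.T
    return u @ root.T


def generate_timeseries(
    partition: Partition,
    within_coupling: float,
    between_coupling: np.ndarray | float,
    T: int,
    noise_sd: float,
    rng_seed: int,
) -> Timeseries:
    """Latent-factor timeseries with planted block correlation structure.

    Node signal = sqrt(within_coupling) * community latent + noise_sd *
    white noise, so pre-noise correlations are ``within_coupling`` within a
    community and ``between_coupling`` (scalar or K x K) across. Expected
    observed |r| within a block exceeds that between blocks whenever
    within > between. Deterministic given ``rng_seed``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if T < 20:
        raise ValueError("T must be >= 20")
    rng = np.random.default_rng(rng_seed)
    K = partition.K
    C = _latent_correlation(K, within_coupling, between_coupling)
    u = _correlated_ar1(T, C, rng)
    x = math.sqrt(within_coupling) * u[:, partition.membership]
    x = x + noise_sd * rng.standard_normal((T, len(partition.node_labels)))
    return Timeseries(x, partition.node_labels)


def _background_items(rng: np.random.Generator) -> np.ndarray:
    # zero-inflated: ~52% of background children are symptom-free, matching
    # a ~45% symptom-free fraction and a whole-sample mean sumscore ~1.7
    if rng.random() < 0.52:
        return np.zeros(7)
    items = (rng.random(7) < 0.35).astype(float)
    while items.sum() >= 6:  # keep background below the clinical cutoff
        items[rng.integers(7)] = 0.0
    return items


def _high_ocs_items(rng: np.random.Generator) -> np.ndarray:
    items = (rng.random(7) < 0.25).astype(float)
    items[rng.integers(7)] = 2.0
    ones = np.flatnonzero(items == 1.0)
    rng.shuffle(ones)
    for i in ones:
        if items.sum() <= 5:
            break
        items[i] = 0.0
    return items


def _probable_ocd_items(rng: np.random.Generator, with_often: bool) -> np.ndarray:
    """Items summing >= 6; ``with_often`` controls whether any item is a 2.

    The no-'often' subtype (six or seven items scored 1) keeps the realized
    high-OCS fraction equal to its nominal prevalence.
    """
    if not with_often:
        items = np.zeros(7)
        items[rng.permutation(7)[: rng.integers(6, 8)]] = 1.0
        return items
    items = rng.choice([0.0, 1.0, 2.0], size=7, p=[0.25, 0.45, 0.30])
    while items.sum() < 6:
        i = rng.integers(7)
        if items[i] < 2:
            items[i] += 1.0
    if not np.any(items == 2.0):
        items[rng.integers(7)] = 2.0
    return items


def generate_phenotypes(
    n: int,
    prevalence: dict | None = None,
    rng_seed: int = 0,
    missing_item_rate: float = 0.02,
) -> list[PhenotypeRecord]:
    """Phenotype records with SOCS items, covariates, and case prevalences.

    Subjects are assigned a latent class (probable OCD / high-OCS /
    background) by the prevalence fractions; items are drawn consistently
    with the class (background subjects never score 'often' and stay below
    the cutoff). A configurable fraction of subjects has exactly one item
    missing, exercising the weighted-sumscore rule. Age ~ N(10.1, 0.6)
    years, sex ~ Bernoulli(0.49), ethnicity three-level, and the adjusted
    CBCL score is negative-binomial with a higher mean in case groups.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prevalence = dict(prevalence or {"probable_ocd": 0.064, "high_ocs": 0.078})
    p_ocd = prevalence.get("probable_ocd", 0.0)
    p_high = prevalence.get("high_ocs", 0.0)
    # fraction of probable-OCD children who also score 'often' somewhere;
    # they count toward the high-OCS budget so realized fractions track
    # their nominal prevalences
    q_often = 0.0 if p_ocd == 0 else min(0.6, p_high / p_ocd)
    p_high_only = max(p_high - p_ocd * q_often, 0.0)
    rng = np.random.default_rng(rng_seed)
    records = []
    for i in range(n):
        u = rng.random()
        if u < p_ocd:
            items = _probable_ocd_items(rng, with_often=rng.random() < q_often)
            cbcl_mean = 24.0
        elif u < p_ocd + p_high_only:
            items = _high_ocs_items(rng)
            cbcl_mean = 20.0
        else:
            items = _background_items(rng)
            cbcl_mean = 13.0
        if rng.random() < missing_item_rate:
            items = items.copy()
            items[rng.integers(7)] = np.nan
        eth = rng.choice(
            ["Dutch", "Non-Dutch Western", "Non-Dutch Non-Western", None],
            p=[0.648, 0.130, 0.205, 0.017],
        )
        # negative binomial with dispersion r=1.3 around the group mean
        r = 1.3
        cbcl = float(rng.negative_binomial(r, r / (r + cbcl_mean)))
        records.append(
            PhenotypeRecord(
                subject_id=f"sub-{i:04d}",
                socs_items=tuple(items),
                age=float(rng.normal(10.1, 0.6)),
                sex=int(rng.random() < 0.492),
                ethnicity=eth,
                cbcl_adj=cbcl,
            )
        )
    return records


def _effect_couplings(spec: CohortSpec) -> np.ndarray:
    """K x K between-coupling matrix for subjects carrying the planted effect."""
    K = spec.n_communities
    B = np.full((K, K), spec.between_coupling)
    eff = spec.effect
    if eff.target == "between_coupling_pair":
        a, b = eff.pair
        if not (0 <= a < K and 0 <= b < K and a != b):
            raise ValueError(f"invalid community pair {eff.pair}")
        B[a, b] -= eff.magnitude
        B[b, a] -= eff.magnitude
    else:  # modularity_shift: segregate all communities
        B -= eff.magnitude
    if np.any(B < -1e-12):
        raise ValueError("effect magnitude would make a coupling negative")
    return np.clip(B, 0.0, None)


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Full synthetic cohort: phenotypes, FD traces and planted timeseries.

    All subjects share the planted partition. Subjects in the effect's
    affected group are generated with the modified couplings. Bit-identical
    given an identical spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    partition, _ = planted_layout(spec.n_nodes, spec.n_communities, spec.thalamic_pairs)
    records = generate_phenotypes(
        spec.n_subjects,
        spec.prevalence,
        rng_seed=int(rng.integers(2**31)),
        missing_item_rate=spec.missing_item_rate,
    )
    effect_b = _effect_couplings(spec) if spec.effect is not None else None
    subjects = []
    for rec in records:
        affected = (
            spec.effect is not None
            and classify_groups(rec.socs_items)[spec.effect.affected_group]
        )
        between = effect_b if affected else spec.between_coupling
        ts = generate_timeseries(
            partition,
            spec.within_coupling,
            between,
            spec.timeseries_length,
            spec.noise_sd,
            rng_seed=int(rng.integers(2**31)),
        )
        # folded-Gaussian FD trace; subject-level means ~0.12 mm put roughly
        # a tenth of subjects past the spike (>20% of volumes > 0.2 mm) or
        # mean-FD (0.25 mm) exclusion rules
        mu = abs(rng.normal(0.10, 0.045)) + 0.02
        fd = np.abs(rng.normal(mu, 0.025, size=spec.timeseries_length))
        subjects.append(
            SyntheticSubject(
                subject_id=rec.subject_id,
                timeseries=ts,
                phenotype=rec,
                planted_partition=partition,
                fd_trace=fd,
            )
        )
    return subjects


def write_cohort(subjects: list[SyntheticSubject], outdir: str | Path, spec: CohortSpec | None = None) -> None:
    """Write phenotypes.tsv, per-subject timeseries and FD traces, the
    planted partition, and a manifest echoing the cohort spec."""
    import pandas as pd

    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    (outdir / "fd").mkdir(exist_ok=True)
    rows = []
    for s in subjects:
        rec = s.phenotype
        rows.append(
            {
                "subject_id": rec.subject_id,
                **{f"socs_item_{i+1}": rec.socs_items[i] for i in range(7)},
                "socs_sum": rec.socs_sum,
                **{k: v for k, v in rec.groups.items()},
                "age": rec.age,
                "sex": rec.sex,
                "ethnicity": rec.ethnicity if rec.ethnicity is not None else "",
                "cbcl_adj": rec.cbcl_adj,
            }
        )
        np.savetxt(
            outdir / "timeseries" / f"{s.subject_id}.tsv",
            s.timeseries.values,
            fmt="%.6g",
            delimiter="\t",
            header="\t".join(s.timeseries.node_labels),
            comments="",
        )
        np.savetxt(outdir / "fd" / f"{s.subject_id}.txt", s.fd_trace, fmt="%.6g")
    pd.DataFrame(rows).to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    part = subjects[0].planted_partition
    pd.DataFrame(
        {"node_label": part.node_labels, "community": part.membership}
    ).to_csv(outdir / "planted_partition.tsv", sep="\t", index=False)
    if spec is not None:
        manifest = {
            "n_subjects": spec.n_subjects,
            "n_nodes": spec.n_nodes,
            "n_communities": spec.n_communities,
            "timeseries_length": spec.timeseries_length,
            "within_coupling": spec.within_coupling,
            "between_coupling": spec.between_coupling,
            "noise_sd": spec.noise_sd,
            "prevalence": dict(spec.prevalence),
            "seed": spec.seed,
            "effect": None
            if spec.effect is None
            else {
                "target": spec.effect.target,
                "magnitude": spec.effect.magnitude,
                "affected_group": spec.effect.affected_group,
                "pair": list(spec.effect.pair) if spec.effect.pair else None,
            },
        }
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
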