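"""End-to-end train/test experiment orchestration and correction arithmetic.

The experiment mirrors a two-scanner replication design: a training cohort
defines feature selections, significant findings and therefore the
testing-sample thresholds; the testing cohort never refits selections.
Hypotheses covered: group effects on the 18 GS summary measures (H1), linear
acquisition-order effects (H2), multivariate brain/behavior PLS for FC (H3a)
and regional variance (H3b), and motion/behavior associations (E1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["bonferroni", "ExperimentConfig", "run_experiment", "cohort_analysis_inputs"]


def bonferroni(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected threshold, rounded to 4 decimals for reporting.

    alpha/54 -> 0.0009, alpha/18 -> 0.0028, alpha/7 -> 0.0071,
    alpha/15 -> 0.0033, alpha/4 -> 0.0125 at alpha = 0.05.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return round(alpha / n_tests, 4)


def bonferroni_exact(alpha: float, n_tests: int) -> float:
    """Full-precision Bonferroni threshold."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class ExperimentConfig:
    """Train/test cohort specs plus analysis options."""

    train_spec: "CohortSpec"        # noqa: F821 - forward ref to synthetic_data
    test_spec: "CohortSpec" = None  # defaults to train_spec with shifted seed
    modes: tuple[str, ...] = ("raw",)
    selection_methods: tuple[str, ...] = ("correlation", "icc", "combined", "dynamic")
    n_perm: int = 500
    n_components: int = 10
    alpha: float = 0.05
    seed: int = 0
    clean: bool = True

    def __post_init__(self):
        if self.test_spec is None:
            self.test_spec = replace(self.train_spec, seed=self.train_spec.seed + 10_007)
        if self.train_spec.seed == self.test_spec.seed:
            raise ValueError("train and test cohort seeds must differ")


def cohort_analysis_inputs(cohort, clean: bool = True, fc_scales=(3, 4, 5), levels: int = 6):
    """Shared per-cohort computations for the experiment.

    Returns a dict with cleaned per-subject data, wavelet FC (Fisher z) and
    variance arrays, GS tables, motion metric means + PCA scores, and the
    behavior matrix.
    """
    from . import gs_metrics, motion_metrics
    from .nuisance import clean_sequence
    from .wavelet import modwt_decompose, wavelet_variance

    spec = cohort.spec
    n_sub = len(cohort.subjects)
    n_seq = spec.n_sequences
    R = spec.n_regions
    data = {}
    for s in cohort.subjects:
        seqs = []
        for q, seq in enumerate(s.sequences):
            raw = seq.values
            if clean:
                cleaned, _ = clean_sequence(raw, s.noise_pool[q], s.motion[q], tr=spec.tr_seconds)
            else:
                cleaned = raw - raw.mean(axis=0)
            seqs.append({"data": cleaned, "raw": raw, "order": seq.sequence_order})
        data[s.subject_id] = seqs

    fc_z = np.empty((n_sub, n_seq, len(fc_scales), R, R))
    variances = np.empty((n_sub, n_seq, len(fc_scales), R))
    for i, s in enumerate(cohort.subjects):
        for q in range(n_seq):
            dec = modwt_decompose(data[s.subject_id][q]["data"].T, levels=levels)
            for si, j in enumerate(fc_scales):
                W = dec.details[j - 1]
                C = np.corrcoef(W)
                np.fill_diagonal(C, 0.0)
                fc_z[i, q, si] = np.arctanh(np.clip(C, -1 + 1e-12, 1 - 1e-12))
                variances[i, q, si] = wavelet_variance(dec, j)

    metric_means = motion_metrics.cohort_motion_metrics(
        [s.motion for s in cohort.subjects], [s.subject_id for s in cohort.subjects]
    )
    pca = motion_metrics.cohort_motion_pca(metric_means, k=5)
    gs_table = gs_metrics.compute_gs_table(data, mode="raw")
    behavior = cohort.behavior
    return {
        "data": data,
        "fc_z": fc_z,
        "variances": variances,
        "gs_table": gs_table,
        "motion_metrics": metric_means,
        "motion_pcs": pca.scores,
        "behavior": behavior,
        "group": cohort.groups(),
    }


def _mean_fc_features(fc_z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sequence-mean edge features (subjects x edges) + per-sequence array."""
    n_sub, n_seq, n_sc, R, _ = fc_z.shape
    iu = np.triu_indices(R, k=1)
    per_seq = fc_z[:, :, :, iu[0], iu[1]].reshape(n_sub, n_seq, n_sc * iu[0].size)
    return per_seq.mean(axis=1), per_seq


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full train/test experiment; returns a nested report dict.

    Deterministic given the config (cohort seeds + analysis seed).
    """
    from . import reliability, selection_pls
    from .gs_metrics import gs_group_regression, linear_order_contrast
    from .synthetic_data import generate_cohort

    report = {"config": {"seed": config.seed, "alpha": config.alpha, "n_perm": config.n_perm}}
    cohorts = {}
    for tag, spec in (("train", config.train_spec), ("test", config.test_spec)):
        cohorts[tag] = cohort_analysis_inputs(generate_cohort(spec), clean=config.clean)

    alpha = config.alpha
    # ----- H1: group effects on the 18 GS measures -------------------------
    h1 = {}
    train_reg = gs_group_regression(
        cohorts["train"]["gs_table"], cohorts["train"]["group"], cohorts["train"]["motion_pcs"], alpha=alpha
    )
    hits = train_reg[train_reg["significant"]]["measure"].tolist()
    h1["training_threshold"] = bonferroni(alpha, 18 * 3)
    h1["training_hits"] = hits
    if hits:
        thr = bonferroni(alpha, len(hits))
        test_reg = gs_group_regression(
            cohorts["test"]["gs_table"], cohorts["test"]["group"], cohorts["test"]["motion_pcs"], alpha=alpha
        ).set_index("measure")
        h1["testing_threshold"] = thr
        h1["replicated"] = [m for m in hits if test_reg.loc[m, "p"] < thr]
    else:
        h1["testing_threshold"] = None
        h1["replicated"] = []
    # effect-size profile correlation across the 18 measures
    test_reg_all = gs_group_regression(
        cohorts["test"]["gs_table"], cohorts["test"]["group"], cohorts["test"]["motion_pcs"], alpha=alpha
    )
    h1["effect_profile_r"] = float(np.corrcoef(train_reg["t"], test_reg_all["t"])[0, 1])
    report["H1"] = h1

    # ----- H2: linear order effects on GS measures -------------------------
    h2 = {"threshold": bonferroni(alpha, 18)}
    for tag in ("train", "test"):
        tidy = cohorts[tag]["gs_table"].per_sequence
        tstats = {}
        for (metric, scale), sub in tidy.groupby(["metric", "scale"]):
            piv = sub.pivot_table(index="subject_id", columns="sequence", values="value")
            con = np.array([linear_order_contrast(row) for row in piv.values])
            t = con.mean() / (con.std(ddof=1) / math.sqrt(con.size))
            tstats[f"{metric}_scale{scale}"] = float(t)
        h2[f"{tag}_t"] = tstats
    report["H2"] = h2

    # ----- H3a/H3b: PLS of FC and variance features ------------------------
    rng = np.random.default_rng(config.seed)
    behavior_cols = [c for c in cohorts["train"]["behavior"].columns]
    Y = {tag: cohorts[tag]["behavior"][behavior_cols].values for tag in ("train", "test")}
    scales_only = {
        tag: cohorts[tag]["behavior"][[c for c in behavior_cols if c.startswith("scale_")]].values
        for tag in ("train", "test")
    }
    for label, array_key in (("H3a", "fc_z"), ("H3b", "variances")):
        block = {}
        if array_key == "fc_z":
            feats_train, per_seq_train = _mean_fc_features(cohorts["train"][array_key])
            feats_test, per_seq_test = _mean_fc_features(cohorts["test"][array_key])
            flat_train, _, _ = reliability.fc_edge_measures(cohorts["train"][array_key])
        else:
            V = {t: np.log(cohorts[t][array_key]) for t in ("train", "test")}
            n_sub, n_seq, n_sc, R = V["train"].shape
            per_seq_train = V["train"].reshape(n_sub, n_seq, n_sc * R)
            per_seq_test = V["test"].reshape(V["test"].shape[0], n_seq, n_sc * R)
            feats_train = per_seq_train.mean(axis=1)
            feats_test = per_seq_test.mean(axis=1)
            flat_train = np.moveaxis(V["train"], (2, 3), (0, 1)).reshape(n_sc * R, n_sub, n_seq)
        iccs = reliability.icc31_many(flat_train)
        n_train_sig = 0
        per_method = {}
        for method in config.selection_methods:
            sel = selection_pls.select_features(
                feats_train, scales_only["train"], method=method, k=30,
                iccs=iccs, per_sequence=per_seq_train,
            )
            Xtr = sel.values(feats_train, per_seq_train)
            Xte = sel.values(feats_test, per_seq_test)
            seed_m = int(rng.integers(2**31 - 1))
            res_tr = selection_pls.pls_permutation(
                Xtr, Y["train"], n_perm=config.n_perm, seed=seed_m, n_comp=config.n_components
            )
            res_te = selection_pls.pls_permutation(
                Xte, Y["test"], n_perm=config.n_perm, seed=seed_m + 1, n_comp=config.n_components
            )
            sig_tr = np.flatnonzero(res_tr.perm_p < alpha)
            n_train_sig += sig_tr.size
            per_method[method] = {
                "train_p": res_tr.perm_p.tolist(),
                "test_p": res_te.perm_p.tolist(),
                "train_significant": sig_tr.tolist(),
                "correspondence_x": selection_pls.correspondence(res_tr, res_te).x_diagonal.tolist(),
            }
        thr = selection_pls.replication_thresholds(n_train_sig, alpha) if n_train_sig else None
        replicated = []
        if thr is not None:
            for method, rm in per_method.items():
                for c in rm["train_significant"]:
                    if rm["test_p"][c] < thr and rm["correspondence_x"][c] > 0.5:
                        replicated.append((method, c))
        block["n_training_significant"] = n_train_sig
        block["testing_threshold"] = thr
        block["replicated"] = replicated
        block["methods"] = per_method
        report[label] = block

    # ----- E1: motion/behavior ---------------------------------------------
    e1_seed = int(rng.integers(2**31 - 1))
    res_motion = selection_pls.pls_permutation(
        cohorts["train"]["motion_metrics"].values, Y["train"], n_perm=config.n_perm,
        seed=e1_seed, n_comp=min(config.n_components, 12),
    )
    report["E1"] = {"train_p": res_motion.perm_p.tolist()}
    report["thresholds"] = {
        "h1_training": bonferroni(alpha, 54),
        "h2": bonferroni(alpha, 18),
    }
    return report
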