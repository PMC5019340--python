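"""End-to-end study-style experiments on synthetic cohorts.

These functions wire the full pipeline together -- generate a cohort, bin,
select pixels, cross-validate the penalty, predict held-out patients,
score agreement -- and are what the reproduction script and the end-to-end
tests run.  Problem sizes are chosen to mirror a realistic margin-assessment
cohort (25
training patients with roughly two thousand annotated pixels each,
glands-dominated class balance) at synthetic-data scale.
"""

from __future__ import annotations

import numpy as np

from . import _solver
from .customized import CustomizedConfig, CustomizedTraining
from .evaluation import agreement_report, confusion_matrix
from .model import MultinomialLassoClassifier
from .preprocess import FeatureMatrix, bin_features, select_pixels
from .synthetic import (
    NoiseModel,
    banded_layout,
    default_class_profiles,
    generate_sample,
    mixed_layout,
    sample_patient_effect,
)

#: Class balance of the default training layout: glands-dominated, stroma
#: scarce, echoing the annotated-pixel balance of clinical cohorts.
DEFAULT_FRACTIONS = {"glands": 0.60, "cancer": 0.30, "stroma": 0.10}


def cohort_feature_arrays(cohort) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Bin every sample and pool the annotated pixels with patient groups."""
    fms, labels, groups = [], [], []
    for sample, mask in cohort:
        fm, lab = select_pixels(bin_features(sample), mask)
        fms.append(fm)
        labels.append(lab)
        groups.append(np.repeat(sample.patient_id, len(lab)))
    return (
        FeatureMatrix.concat(fms),
        np.concatenate(labels),
        np.concatenate(groups),
    )


def pure_cohort_experiment(
    seed: int,
    n_train: int = 25,
    n_test: int = 3,
    grid: tuple[int, int] = (45, 45),
    fractions: dict[str, float] | None = None,
    n_lambdas: int = 12,
    lambda_min_ratio: float = 1e-3,
    max_cv_pixels_per_group: int = 100,
) -> dict:
    """Train on a clear-diagnosis cohort, evaluate held-out patients.

    Generates ``n_train + n_test`` patients of banded pure-class samples,
    runs leave-one-patient-out CV on the training patients to choose the
    penalty, refits on all their pixels, and scores pixel agreement on the
    ``n_test`` held-out patients.  Returns per-class and overall held-out
    agreement percentages plus fit diagnostics.

    Samples are generated and binned one at a time so only the 2,220-feature
    matrices are ever held in memory, never the full cohort of raw
    13,320-channel spectra.
    """
    from .synthetic import sample_patient_effect as _spe

    layout = banded_layout(grid, fractions or DEFAULT_FRACTIONS)
    profiles = default_class_profiles()
    noise = NoiseModel()
    ss = np.random.SeedSequence(seed)

    def _patient_features(child, patient_id):
        eff_rng = np.random.default_rng(child.spawn(1)[0])
        effect = _spe(profiles, noise.patient_effect_sd, eff_rng)
        rng = np.random.default_rng(child.spawn(1)[0])
        sample, mask = generate_sample(
            layout, profiles, noise, rng,
            sample_id=f"{patient_id}S0", patient_id=patient_id,
            patient_effect=effect,
        )
        fm_i, lab_i = select_pixels(bin_features(sample), mask)
        return fm_i, lab_i

    children = ss.spawn(n_train + n_test)
    fms, labs, grps = [], [], []
    test_fms, test_labs = [], []
    for p, child in enumerate(children):
        pid = f"P{p:03d}"
        fm_i, lab_i = _patient_features(child, pid)
        if p < n_train:
            fms.append(fm_i)
            labs.append(lab_i)
            grps.append(np.repeat(pid, len(lab_i)))
        else:
            test_fms.append(fm_i)
            test_labs.append(lab_i)
    fm = FeatureMatrix.concat(fms)
    labels = np.concatenate(labs)
    groups = np.concatenate(grps)
    del fms, labs, grps
    model = MultinomialLassoClassifier(fm, labels, groups=groups)
    # the CV search only ranks penalties, so it runs at a relaxed solver
    # tolerance with capped iterations; the final refit is solved tight
    cv = model.fit_cv(
        n_lambdas=n_lambdas,
        lambda_min_ratio=lambda_min_ratio,
        max_pixels_per_group=max_cv_pixels_per_group,
        seed=seed,
        tol=1e-4,
        max_iter=250,
        refit_tol=1e-5,
        refit_max_iter=1500,
    )
    fm_te = FeatureMatrix.concat(test_fms)
    labels_te = np.concatenate(test_labs)
    pred = cv.fit_.predict(fm_te)
    cm = confusion_matrix(labels_te, pred.labels)
    report = agreement_report(cm)
    return {
        "per_class_agreement_pct": dict(report.per_class_agreement),
        "overall_agreement_pct": report.overall_agreement,
        "confusion": cm,
        "chosen_lambda": cv.chosen_lambda,
        "n_selected_features": cv.fit_.nonzero_count,
        "n_train_pixels": len(labels),
        "n_test_pixels": len(labels_te),
        "cv": cv,
    }


#: m/z positions of the batch-shift contaminant peaks: spurious intensity at
#: the polyunsaturated-FA markers (arachidonic 303.3, adrenic 331.2) added to
#: every spectrum of an affected acquisition batch.
BATCH_SHIFT_MZ = (303.3, 331.2)

#: Amplitude range (ion counts) of the batch shift, drawn per affected sample.
BATCH_SHIFT_AMPLITUDE = (15.0, 30.0)


def _batch_peaks(rng) -> list[tuple[float, float, float]]:
    amp = float(rng.uniform(*BATCH_SHIFT_AMPLITUDE))
    return [(mz, amp, 0.15) for mz in BATCH_SHIFT_MZ]


def mixed_customized_experiment(
    seed: int,
    n_train: int = 8,
    n_shifted_train: int = 2,
    train_grid: tuple[int, int] = (20, 20),
    n_mixed: int = 20,
    mixed_grid: tuple[int, int] = (16, 16),
    mixed_composition=(0.20, 0.0, 0.80),
    n_lambdas: int = 10,
    lambda_min_ratio: float = 1e-3,
    config: CustomizedConfig | None = None,
) -> dict:
    """Customized vs global predictions on batch-shifted mixed samples.

    The cohort has batch structure: ``n_shifted_train`` of the ``n_train``
    training patients (equal-thirds pure-class bands) and *all* test samples
    carry the additive instrument batch shift (spurious peaks at the
    polyunsaturated-FA markers, amplitude drawn per sample).  The global
    model, a single linear compromise across batches, over-calls cancer on
    shifted stroma; customized training clusters shifted test pixels with
    the shifted training patients' stroma and its local model separates the
    contaminant level from genuine cancer.

    Test: ``n_mixed`` samples, each from a fresh patient, of one
    mixed-histology region (default 20% tumor cells in 80% stroma).  For
    each sample the experiment records the percent of pixels predicted
    cancer by the global CV model and by customized training, against the
    realized truth percentage.
    """
    ss = np.random.SeedSequence(seed)
    layout = banded_layout(
        train_grid, {"cancer": 1 / 3, "glands": 1 / 3, "stroma": 1 / 3}
    )
    profiles = default_class_profiles()
    noise = NoiseModel()
    train = []
    for i, child in enumerate(ss.spawn(n_train)):
        rng = np.random.default_rng(child)
        effect = sample_patient_effect(profiles, noise.patient_effect_sd, rng)
        peaks = _batch_peaks(rng) if i < n_shifted_train else None
        train.append(
            generate_sample(
                layout, profiles, noise, rng,
                sample_id=f"P{i:03d}S0", patient_id=f"P{i:03d}",
                patient_effect=effect, batch_peaks=peaks,
            )
        )
    fm, labels, groups = cohort_feature_arrays(train)

    cfg = config or CustomizedConfig(
        n_clusters=3,
        seed=int(ss.generate_state(2)[1] % (2**31)),
        n_lambdas=n_lambdas,
        lambda_min_ratio=lambda_min_ratio,
        max_cv_pixels_per_group=100,
    )
    ct = CustomizedTraining(fm, labels, groups, cfg)

    mixed = mixed_layout(mixed_grid, mixed_composition)
    rows = []
    for i, child in enumerate(ss.spawn(n_mixed)):
        rng = np.random.default_rng(child)
        effect = sample_patient_effect(profiles, noise.patient_effect_sd, rng)
        sample, mask = generate_sample(
            mixed, profiles, noise, rng,
            sample_id=f"MIX{i:02d}", patient_id=f"Q{i:03d}",
            patient_effect=effect, batch_peaks=_batch_peaks(rng),
        )
        fm_te, lab_te = select_pixels(bin_features(sample), mask)
        truth_pct = 100.0 * float((lab_te == "cancer").mean())
        global_pct = 100.0 * ct.global_fit.predict(fm_te).class_fraction("cancer")
        res = ct.fit_predict(fm_te)
        custom_pct = 100.0 * res.prediction.class_fraction("cancer")
        rows.append(
            {"sample_id": sample.sample_id, "truth_pct": truth_pct,
             "global_pct": global_pct, "customized_pct": custom_pct,
             "n_local_models": sum(not g for g in res.used_global.values())}
        )
    truth = np.array([r["truth_pct"] for r in rows])
    glob = np.array([r["global_pct"] for r in rows])
    cust = np.array([r["customized_pct"] for r in rows])
    return {
        "samples": rows,
        "global_mean_abs_error_pct": float(np.abs(glob - truth).mean()),
        "customized_mean_abs_error_pct": float(np.abs(cust - truth).mean()),
        "global_fit": ct.global_fit,
        "customized_model": ct,
    }


def solver_oracle_experiment(seed: int, n_problems: int = 20) -> dict:
    """Cross-check the proximal solver against a generic convex optimizer.

    Random small multinomial problems (up to 6 features, up to 60 points);
    reports the worst relative objective gap (solver minus oracle) and the
    worst KKT violation at the solver's solutions.
    """
    rng = np.random.default_rng(seed)
    worst_gap = 0.0
    worst_kkt = 0.0
    done = 0
    while done < n_problems:
        n = int(rng.integers(20, 61))
        p = int(rng.integers(2, 7))
        K = int(rng.integers(2, 4))
        X = rng.normal(size=(n, p))
        beta = 2.0 * rng.normal(size=(p, K))
        Z = X @ beta
        prob = np.exp(Z - Z.max(axis=1, keepdims=True))
        prob /= prob.sum(axis=1, keepdims=True)
        y = np.array([rng.choice(K, p=row) for row in prob])
        if len(set(y)) < 2:
            continue
        Y = _solver.one_hot(y, tuple(range(K)))
        mean, scale = _solver.standardization(X)
        lam = float(rng.uniform(0.005, 0.3))
        W, b = _solver.fit_l1_multinomial(
            X, Y, lam, mean, scale, tol=1e-9, screen=False
        )
        obj = _solver.objective(X, Y, W, b, lam, mean, scale)
        _, _, obj_oracle = _solver.oracle_fit(X, Y, lam, mean, scale)
        worst_gap = max(worst_gap, (obj - obj_oracle) / abs(obj_oracle))
        GW, _, _ = _solver._grad(X, Y, W, b, mean, scale)
        worst_kkt = max(worst_kkt, _solver.kkt_violation(GW, W, lam))
        done += 1
    return {
        "n_problems": n_problems,
        "max_relative_objective_gap": float(worst_gap),
        "max_kkt_violation": float(worst_kkt),
    }
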