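# kernem

Anatomically guided kernelized expectation–maximization (KEM/HKEM) PET
reconstruction, with a synthetic abdominal-aneurysm phantom and the
quantitative analysis pipeline used to compare reconstruction algorithms
for aneurysm detection.

## The problem

[18F]-NaF PET can detect active microcalcification in the wall of an
abdominal aortic aneurysm (AAA) before the aneurysm's diameter alone
predicts risk. But the lesions are small, PET resolution is poor, and the
spine — very hot under a bone tracer — sits right behind the aorta, so
partial-volume spill-in and spill-out corrupt exactly the quantity
clinicians read: the maximum target-to-blood-pool ratio

    TBR_max(T) = SUV_max(T) / SUV_mean(B)

for the aneurysm target ROI `T` normalised by the vena-cava blood pool `B`,
and the percentage uptake increase over the non-aneurysmal aorta `A`:

    Increase = 100 · (TBR_max(T) − TBR_max(A)) / TBR_max(A),

with an increase above 25% (strict) classifying a subject as AAA-positive.

Edge-preserving kernel reconstructions attack this at the source. The image
is represented through a kernel expansion λ = Kα, and the EM update is run
on the coefficients α:

    α⁽ⁿ⁺¹⁾ = α⁽ⁿ⁾ · [Kᵀ Pᵀ (y / (P K α⁽ⁿ⁾ + s))] / [Kᵀ Pᵀ 1]

where `P` is the system model (projector with PSF), `y` the measured
counts and `s` the additive scatter+randoms term. The kernel row for voxel
j weights its feature-nearest neighbours f by

    k_m(v_j, v_f) = exp(−‖v_j−v_f‖²/2σ_m²) · exp(−‖x_j−x_f‖²/2σ_dm²)

with patch features `v` from a CT-like guidance image (**KEM**), optionally
multiplied elementwise by the same construction on the current iterate
(**HKEM**, K = K_m·K_p⁽ⁿ⁾), so functional edges absent from the anatomy —
microcalcification is often invisible on CT — are still preserved. The
baseline is OSEM with a 5 mm Gaussian post-filter (**OSEM+G**).

The package provides:

- `kernem.phantom` — 2-D abdominal phantoms (hot spine, aneurysmal aorta
  with calcified lesions, normal aorta, vena cava) and whole cohorts;
- `kernem.forward_model` — parallel-beam projector with Gaussian PSF
  (exact adjoint pair), additive term, Poisson data, ordered subsets;
- `kernem.kernel` — sparse anatomical/functional/hybrid kernel operators;
- `kernem.recon` — MLEM/OSEM(+G), KEM and HKEM;
- `kernem.metrics` — TBR_max, uptake increase, 25% classification, CoV,
  iteration selection (highest true-positive count) and the
  kernel-parameter sweep rule (highest TBR at fixed CoV);
- `kernem.cohort_stats` — paired t-tests, ROC with DeLong AUC inference,
  Pearson correlation, logistic regression, balanced sub-sampling;
- `kernem.io_cli` — NIfTI/CSV/YAML I/O and the `kernem` CLI
  (`simulate | reconstruct | analyze | stats | run`).

## Worked example

```python
from kernem.forward_model import SystemModel, simulate_counts, uniform_additive
from kernem.metrics import record_from_image
from kernem.phantom import PhantomSpec, generate_subject
from kernem.recon import ReconConfig, reconstruct

subj = generate_subject(PhantomSpec(lesion_count=1, lesion_contrast=2.5, seed=7))
model = SystemModel((64, 64), 3.0, n_angles=63, psf_fwhm_mm=4.4)
additive = uniform_additive(model, 1.5e5)
data = simulate_counts(subj.activity_truth, model, additive,
                       total_counts=5e5, seed=11)
for algo in ("osem", "kem", "hkem"):
    res = reconstruct(data, model, additive, subj.anatomical,
                      ReconConfig(algorithm=algo, n_subsets=7, n_iterations=4))
    rec = record_from_image(res.images[-1], subj.rois, subj.subject_id,
                            subj.label, subj.aneurysm_diameter, algorithm=algo)
    print(f"{algo:5s} TBR(T)={rec.tbr_T:.2f} TBR(A)={rec.tbr_A:.2f} "
          f"increase={rec.increase:.1f}% positive={rec.predicted_positive}")
```

prints (this phantom's single lesion is CT-invisible, so the functional
kernel is what recovers it):

```
osem  TBR(T)=1.83 TBR(A)=1.25 increase=46.0% positive=True
kem   TBR(T)=1.95 TBR(A)=1.26 increase=54.0% positive=True
hkem  TBR(T)=2.01 TBR(A)=1.26 increase=59.2% positive=True
```

The kernel methods recover more lesion uptake than the post-filtered
baseline (higher TBR(T) at essentially unchanged TBR(A)), which is the
mechanism that turns into higher detection sensitivity at cohort level.

A full file-based experiment (cohort CSV + NIfTI volumes + statistics
report) is one command:

```bash
kernem run --config my_config.yaml --out-dir results/experiment
```

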