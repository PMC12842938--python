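# dynmodal

Dynamic multimodal time-series classification for audio-visual behavioral
data, built around two ideas:

1. **Multi-scale temporal experts.** Each univariate feature channel is
   patched at two resolutions. Low-resolution patches feed a selective
   state-space (Mamba-style) block that models long-term trends through the
   input-dependent recurrence `h_t = Ā_t ⊙ h_{t-1} + B̄_t x_t`,
   `y_t = ⟨C_t, h_t⟩`; high-resolution patches feed a Local Window
   Transformer whose self-attention is restricted to a band
   `|i − j| ≤ ⌊w/2⌋`. A learned two-way router weights the two scales,
   `[p_L, p_S] = softmax(W z_B + b)`, and the weighted token sequences are
   concatenated.
2. **Resource-aware dynamic fusion.** A lightweight audio probe scores four
   processing pathways of increasing cost (audio-only 0.6 GFLOPs, audio +
   compressed video 1.0, audio + full video 1.6, deep audio-visual fusion
   2.3); exactly one expert runs per sample. A stack of fusion cells then
   each selects one of four operations (audio-internal → deep co-attention).
   Training optimizes

   `L = L_task + λ ( Σ_i p_i C(E_i) + Σ_j Σ_k π_{j,k} C(O_k) )`

   with straight-through Gumbel-Softmax decisions, so the gates learn to
   spend computation only where it buys accuracy.

The intended application is screening-style classification of behavioral
feature sequences (e.g. frame-level acoustic descriptors and facial
landmarks/action units) where subjects differ in both slow drifts and
short-lived bursts, and where inference cost matters. The package ships a
synthetic-data generator that emulates these feature shapes with
controllable trend/fluctuation signal, modality informativeness, noise,
class imbalance and missingness, plus the evaluation stack: six metrics
(accuracy, precision, recall, F1, unweighted accuracy, weighted F1),
pooled t-test significance comparison with Cohen's d and Bonferroni
correction, robustness sweeps, and path-usage/cost reporting.

The model and training stack run on a small reverse-mode autodiff engine
over float64 numpy arrays (`dynmodal.nn`), which also provides the
elementary-operation counter behind the analytic cost model.

## Worked example

```python
import numpy as np
from dynmodal import GeneratorConfig, generate_dataset, RunConfig
from dynmodal.training import train_model
from dynmodal.metrics import compute_metrics, path_distribution

samples = generate_dataset(GeneratorConfig(
    n_samples=200, T_a=48, D_a=4, T_v=48, D_v=4,
    trend_strength=1.5, fluctuation_strength=1.0,
    informative_modality="audio", noise_sd=0.3, seed=7))

config = RunConfig(
    d_model=12, patch_long_len=12, patch_long_stride=12,
    patch_short_len=4, patch_short_stride=2,
    mamba_hidden_dim=24, mamba_state_dim=4, mamba_conv_kernel=4,
    lwt_heads=2, lwt_head_dim=6, lwt_ff_dim=24, lwt_window=5, lwt_layers=1,
    lwt_max_len=64, n_fusion_units=2, cost_lambda=0.01,
    lr=3e-3, batch_size=16, patience=6, max_epochs=20, seed=1)

model, history, split = train_model(samples, config)
test = [s for s in samples if s.sample_id in set(split.test)]
pred = model.predict([s.audio for s in test], [s.video for s in test])
report = compute_metrics(np.array([s.label for s in test]), pred)
print(round(report.accuracy, 3), round(report.f1, 3))
print(path_distribution(model, samples))
```

On this seed the run prints:

```
1.0 1.0
{'fractions': {'path_1': 0.0, 'path_2': 1.0, 'path_3': 0.0, 'path_4': 0.0},
 'mean_nominal_cost': 1.0000015379999998, 'mean_analytic_ops': 153986.0,
 'n_samples': 200}
```

Test accuracy and F1 are 1.0 — the audio trend signal is fully separable —
and after training every sample is routed through the cheap
audio-plus-compressed-video pathway (nominal cost ≈ 1.0 GFLOPs per sample
versus 2.3 for the deep pathway), which is the resource-aware loss doing
its job on audio-informative data.

The same pipeline is available from the shell:

```bash
dynmodal simulate --out data.h5 --n-samples 200 --informative-modality audio
dynmodal train --container data.h5 --config config.yaml --checkpoint model.npz
dynmodal evaluate --checkpoint model.npz --container data.h5
dynmodal report-paths --checkpoint model.npz --container data.h5
dynmodal perturb --container data.h5 --out noisy.h5 --spec noise.yaml
dynmodal compare --a runs_a.json --b runs_b.json --n-comparisons 7
```

## Layout

| Module | Contents |
| --- | --- |
| `dynmodal.nn` | autodiff tensor, layers, Adam, op counter |
| `dynmodal.data` | sample/dataset types, HDF5+manifest and CSV containers, splits |
| `dynmodal.simulate` | synthetic generator, noise/disturbance/missingness protocols |
| `dynmodal.patching` | multi-scale patch slicing, PTS resolution |
| `dynmodal.ssm` | selective scan oracle + block |
| `dynmodal.attention` | banded windowed attention, transformer blocks |
| `dynmodal.router` | per-modality multi-scale encoder + long-short router |
| `dynmodal.fusion` | path gate, experts E1–E4, fusion cells O1–O4, cost model |
| `dynmodal.model` | end-to-end classifier |
| `dynmodal.training` | losses, Gumbel-Softmax/STE, annealing, training loop |
| `dynmodal.metrics` | six metrics, significance, robustness sweeps, reports |
| `dynmodal.cli` | `dynmodal` command-line entry point |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
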