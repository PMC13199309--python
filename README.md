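# predmap

A computational model of how hippocampal **predictive maps** can emerge
from diverse entorhinal inputs, for researchers in computational
neuroscience and reinforcement learning.

The model has two stages. Medial-entorhinal spatial codes (grid cells,
boundary-tuned inputs) and lateral-entorhinal contextual codes (object
cells, pre-/post-reward cells) feed a **non-negative sparse coding** layer

```
min_{A ≥ 0, s_h ≥ 0}  ‖s_e − A·s_h‖²₂ + β‖s_h‖₁
```

solved online by the locally competitive algorithm (LCA), which produces
place-cell-like activity `s_h`. A second layer learns **successor
features** over those codes with the TD(0) rule

```
p_h = Mᵀ s_h,    M ← M + η·s_h,t (s_h,t + γ p_h,t+1 − p_h,t)ᵀ,
```

so `p_h` estimates the discounted expected future activity
ψ(s) = E[Σ_t γᵗ φ(s_t)] with φ = s_h. An actor–critic module turns the
predictive map into behavior: a reward vector `R ← R + α(r·s_h − R)` and
value `V = p_hᵀR` supply TD errors `δ = r + γV' − V` that train
population-vector (2D) or Gaussian (1D) MLP policies by policy gradient.

Four self-contained studies reproduce signature phenomena of hippocampal
physiology: backward-skewed place fields under directed running, the
necessity of the predictive layer for water-maze navigation, and
object- and reward-centered overrepresentation of place fields.

## Worked example

```python
from predmap.experiments import run_skew2d

res = run_skew2d(seed=1)
print(f"sparse   |skew|: {res['skew_sparse']['mean']:.3f} ± {res['skew_sparse']['sd']:.3f} m")
print(f"predictive |skew|: {res['skew_predictive']['mean']:.3f} ± {res['skew_predictive']['sd']:.3f} m")
print(f"lag-1 autocorr: sparse {res['autocorr_sparse'].mean():.3f}, "
      f"predictive {res['autocorr_predictive'].mean():.3f}")
print(f"Welch p (skew): {res['welch_skew'].pvalue:.2e}")
```

prints (seed 1):

```
sparse   |skew|: 0.020 ± 0.011 m
predictive |skew|: 0.109 ± 0.031 m
lag-1 autocorr: sparse 0.303, predictive 0.663
Welch p (skew): 3.13e-60
```

Reading: an agent runs upward through a periodic 1 m arena while the
successor matrix is learned. Sparse-layer place fields stay compact and
symmetric (skew ≈ the mapping noise floor, 2 cm), whereas predictive-layer
fields smear opposite to travel — their center of mass sits ~11 cm below
the peak — and their activity is far more temporally persistent. That
asymmetry is the 2D analog of the backward skew of place fields on linear
tracks, the signature of a predictive code.

The same API drives the other studies
(`run_watermaze`, `run_objects2d`, `run_reward1d`), and a thin CLI wraps
them:

```bash
predmap run skew2d --seed 1 --outdir out/
predmap run reward1d --seed 1 --scale 0.5 --outdir out/
```

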