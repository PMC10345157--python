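# spindlesim

Can the nervous system tell limb movements apart from muscle-spindle
firing alone?  `spindlesim` is a self-contained computational testbed for
that question.  It simulates a planar two-joint limb (a simplified cat
hindlimb: thigh 90 mm, shank 100 mm, hip fixed at the root) actuated by
four musculotendons — anterior biceps (AB), iliopsoas (IL), vastus
lateralis (VL) and semitendinosus (SM) — tracing five closed end-point
trajectories (circle, line, oscillatory, lemniscate, square) forward and
in reverse.  Each movement drives an intrafusal-fiber muscle-spindle
model (bag1, bag2, chain) that emits primary (Ia, velocity-sensitive)
and secondary (II, length-sensitive) afferent firing rates, giving an
8-channel ensemble (4 muscles × {Ia, II}) of 200 samples per 1-second
movement cycle.

The analysis then asks whether pairs of movements are *discriminable*
from these ensembles.  For each of the 45 unordered pairs of the ten
task-direction conditions, the package computes the maximum over
circular time lags τ of the normalized cross-correlation of the two
multichannel blocks,

    R(τ) = ⟨a_τ , b⟩ / (‖a‖ ‖b‖),

and calls a pair discriminable when max_τ R(τ) < 0.5.  This is done in
the raw 8-D signal space and again after pre-processing with principal
component analysis (centering only, covariance C = XᵀX/n, fitted on the
pooled 2000 × 8 matrix, top k = 3 components; per-muscle analyses use
the 2-channel blocks and k = 2).  Because raw firing rates are
non-negative and share a common baseline structure, raw-space
correlations cluster in the high positive band; PCA removes the pooled
mean pattern, so the same statistic spreads over the full [−1, 1] range
and movements become far easier to tell apart — dimensionality
reduction acts as the "pre-processing at the edge" that makes
proprioceptive percepts usable.  A span metric (bandwidth of the 45
correlation values over the total range of 2), similarity confusion
matrices, a hand-rolled K-means++ clustering baseline and a paired
Wilcoxon signed-rank test complete the report.

Intended users: computational neuroscientists and neuromechanists who
want a small, fully inspectable pipeline from limb kinematics to
population afferent statistics, with every stage exposed as a plain
function over NumPy arrays.

## Worked example

```bash
spindlesim run-all --out demo
```

prints, with the default configuration (passive spindle, γ = 0):

```
combined discriminability: raw 0% (0/45) -> pca 53% (24/45)
report written to demo/report.json
```

Meaning: in the raw 8-channel space not a single one of the 45 movement
pairs falls below the 0.5 correlation threshold (every pair looks alike:
the shared firing baseline dominates, correlation span only 23.3% of the
possible range), while after projection onto the top three pooled
principal components (96.0% of variance; PC1 77.3%, PC2 15.6%,
PC3 3.1%) 24 of 45 pairs become discriminable and the correlation span
widens to 52.1%.  The same improvement holds for every single muscle
(AB 0→36%, IL 0→36%, VL 0→58%, SM 0→58%) and is statistically
significant under the paired Wilcoxon signed-rank test
(p ≈ 1.1 × 10⁻⁸ for the combined set).  The `demo/` directory holds the
stage artifacts: end-point trajectories, joint angles, normalized
fascicle kinematics, afferent ensembles (CSV + JSON sidecars), the PCA
model and scores, the 45-pair correlation tables and the 10 × 10
confusion matrix (raw below the diagonal, PCA above).

The same pipeline is available as a library:

```python
import spindlesim as ss

report = ss.run_experiment()                # default study design
print(report.discriminability["pca_3d"]["percent_rounded"])   # 53
```

Everything is configurable through a YAML file (`spindlesim run-all
--config my.yaml`): task geometry, limb segment lengths, the muscle
moment-arm table, intrafusal constants, fusimotor drives, PCA dimensions
and the correlation threshold.  `spindlesim validate --config my.yaml`
checks a configuration (Table consistency, reachability of every task
sample) before running.

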