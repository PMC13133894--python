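# clubkit

Digital clubbing — bulbous enlargement of the fingertips — is one of the few
visible signs of chronic cardiopulmonary disease, and its bedside assessment
(the Lovibond profile-angle inspection) is notoriously subjective. clubkit is
a desk-scale toolkit that mirrors an automated smartphone screening cascade
for clubbing: it segments a lateral fingertip-profile image, gates the
capture distance, localizes the three anatomical landmarks around the nail
base, computes the Lovibond angle, and grades severity on the standard
four-level clinical scale. It is aimed at researchers who want a fully
testable, dependency-light reference implementation of the geometry and
evaluation layers of such a system — the parts that are usually hidden
inside a mobile app and a trained network.

## The measurement

Three landmarks are placed in the profile view: **A** on the nail matrix,
**B** on the proximal nail fold (the vertex), **C** on the nail plate. With
the finger in a canonical pose (tip → +x, dorsal side up), u = B − A,
v = C − B, and τ the signed angle from u to v (positive toward the palm),
the Lovibond angle is

    θ = 180° − τ.

Severity follows the clinical thresholds: **normal** θ ≤ 160°, **mild**
160° < θ < 180° − ε, **moderate** |θ − 180°| ≤ ε, **severe** θ > 180° + ε
(ε = 1° by default; the published criteria give single angles for normal
and moderate, which are widened to intervals so every angle maps to exactly
one grade). A binary clubbing-vs-normal stage uses the same 160° cutoff and
a negative decision bypasses grading entirely.

Because no clinical images can be redistributed, the package ships a
synthetic renderer whose Lovibond angle, landmarks, grade, bounding box and
capture distance are known exactly *before* rasterization; every stage of
the cascade is tested against it. The reference evaluation's printed
confusion matrices are packaged as fixtures, and the metric suite
reproduces their published metric tables. See `docs/methods.md` for the
model, conventions, and limitations.

## Worked example

```python
import clubkit as ck

# render a moderately clubbed finger seen at 5 cm
spec = ck.FingerProfileSpec(lovibond_angle_deg=184.5, tip_bulb_ratio=1.5,
                            distance_cm=5.0, seed=3)
sample = ck.render_finger_profile(spec)

result = ck.assess(sample.image)
print(result.status, result.gate.status,
      round(result.gate.estimated_distance_cm, 2))
print(result.clubbing_detected, str(result.grade),
      round(result.angle.theta_deg, 2))
```

prints

```
ok accept 4.96
True severe 184.5
```

The capture gate accepted the frame (estimated 4.96 cm against a true
5.0 cm, inside the 4–7 cm band), the binary stage detected clubbing
(θ > 160°), and the measured Lovibond angle of 184.5° — matching the
constructed 184.5° to two decimals — falls above the 181° moderate/severe
boundary, so the finger is graded severe.

The same pipeline is available from the shell:

```bash
clubkit generate -n 50 --seed 1 -o data/          # images + truth sidecars
clubkit assess data/ -o results.jsonl --csv summary.csv
clubkit evaluate --truth data/manifest.csv --pred summary.csv -o metrics.csv
clubkit fixtures show table12                     # packaged reference matrix
```

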