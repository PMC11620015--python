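# ccfdgrid

Grid-based quantification of **choriocapillaris flow deficits (CCFDs)** on
en-face swept-source OCT angiography, with the repeatability statistics
needed to call longitudinal change real.

The choriocapillaris is the capillary monolayer just below Bruch's membrane
(BM) that supplies the RPE and photoreceptors. On OCTA its dropout appears
as *flow deficits*: en-face pixels whose flow signal falls below a global
threshold. Tracking local CCFD change over time — e.g. under a resolving
druse — requires masking confounding lesions, compensating OCT signal
attenuation, registering visits, restricting to the shared scan region, and
knowing how big a change must be before it exceeds test–retest noise. This
package implements that whole workflow for 6×6-mm (500×500-px, 12-µm
spacing) scans, plus a synthetic-eye generator with known ground truth so
every stage is testable without clinical data.

## What it computes

**Per scan** (`ccfd_quant`): the CC slab (a 16-µm slab starting 4 µm below
BM) is projected en face from the volume; the flow image is compensated for
shared multiplicative attenuation by dividing by the smoothed CC structure
image; retinal-vessel projection artifacts and operator-supplied lesion
masks (hyperreflective foci, calcified drusen, hypertransmission defects,
…) are excluded; the remaining pixels are thresholded with a global
2-cluster Fuzzy C-means; deficits with greatest linear dimension < 24 µm
(physiological intercapillary voids and speckle) are removed.

**Per visit set** (`align_grid`): scans are rigidly registered on their
retinal-vasculature en-face images (first scan = baseline frame); the
per-scan combined masks and off-overlap regions merge into one *integrated
mask* applied identically everywhere; ROIs are 3-mm and 5-mm fovea-centered
circles and a grid of complete 74×74-px (≈0.9×0.9 mm) boxes tiled outward
from a target box (25 boxes fovea-centered; up to 36 over all offsets).
CCFD% = 100 × deficit pixels / valid pixels per ROI; grid totals pool
pixels across boxes.

**Statistics** (`reliability`): nested random-intercept variance components
(closed-form nested ANOVA when balanced, REML otherwise);
ICC = (σ²_total − σ²_residual)/σ²_total with a parametric-bootstrap CI;
MDC95 = √2 × 1.96 × σ_residual, the smallest between-visit change
distinguishable from repeat-scan noise at 95% confidence; mixed-model group
contrasts with Tukey (studentized-range) adjustment; and per-box
significance calls |ΔCCFD%| > MDC95.

## Worked example: a resolving druse

A druse shadows the choriocapillaris beneath it, inflating CCFD% without any
true perfusion change. When the druse resolves between visits, the
*uncompensated* target-box CCFD% drops by far more than the box-level MDC95
(3.93%), while the *compensated* measurement — which removed the shadow at
both visits — stays flat:

```python
import ccfdgrid as cg

cfg = cg.SimulationConfig(seed=7)
_, _, _, _, truth = cg.simulate_eye(cfg)
baseline, followup, druse_center = cg.simulate_drusen_resolution_pair(truth)

for mode in ("off", "divide"):
    qc = cg.QuantConfig(compensation=cg.CompensationConfig(mode=mode))
    scans = []
    for bundle in (baseline, followup):
        fd, combined = cg.quantify_scan(
            bundle.flow, bundle.structure, bundle.retina, bundle.masks, qc
        )
        scans.append(cg.QuantifiedScan(bundle.retina, fd, combined, bundle.metadata))
    result = cg.measure_visit_set(scans, center_px=druse_center)
    boxes = result.table[result.table.roi_type == "box"]
    piv = boxes.pivot_table(index="roi_id", columns="visit_id", values="ccfd_percent")
    delta = piv["V001"] - piv["V000"]
    target = result.grid.target_box.box_id
    print(f"compensation={mode!r}: target-box dCCFD% = {delta[target]:+.2f}, "
          f"mean |dCCFD%| controls = {delta.drop(target).abs().mean():.2f}")
```

prints

```
compensation='off': target-box dCCFD% = -59.47, mean |dCCFD%| controls = 0.36
compensation='divide': target-box dCCFD% = -0.83, mean |dCCFD%| controls = 0.19
```

Without compensation the resolving shadow masquerades as a −59-point
perfusion change (far beyond the 3.93% detectability limit); with
compensation the change is −0.8 points — measurement noise — and the 24
surrounding control boxes are stable under both modes.

The same stages are available as a CLI (`ccfdgrid simulate / quantify /
register / grid / reliability / change`); each run writes a JSON manifest
with inputs, config hash and seed.

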