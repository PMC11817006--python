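# thermoresp

Non-contact respiratory pattern analysis from side-view thermal video, with a
screening classifier for obstructive airway disease.

The pipeline quantifies breathing from two regions of interest: a **chest ROI**
whose mean vertical optical flow drives an inspiration/expiration phase state
machine, and a **mouth ROI** where the warm exhalation plume is measured by
counting pixels that brighten between consecutive frames (counted only while
the chest is in expiration). Each subject's 40-second trace is reduced to four
features — total respiratory volume (TRV, accumulated plume pixels), average
distance between expirations (ADE), average distance between inspirations
(ADI), and total respiratory rate (TRR) — which are Z-scaled, combined with a
positive weighted sum, and thresholded at the Youden-optimal point of the
in-sample ROC curve. Weights are selected by a seeded random search over an
integer grid with Youden / accuracy / recall criteria.

Because no public recordings exist, the package includes a synthetic thermal
video generator (`thermoresp.synthetic`) that renders a textured chest band
with programmable vertical motion and a raised-cosine exhalation plume, plus
salt-and-pepper / Gaussian / drifting-warm-blob noise, with frame-accurate
ground truth for every rendered video.

## Modules

| module | purpose |
| --- | --- |
| `thermoresp.synthetic` | ground-truth-annotated synthetic videos and two-group feature tables |
| `thermoresp.preprocess` | normalize → median (5×5) → Gaussian (5×5) → bilateral (9×9) denoising chain |
| `thermoresp.tracker` | optical-flow phase detection + plume pixel counting over the 40 s window |
| `thermoresp.features` | TRV / ADE / ADI / TRR extraction from a breath trace |
| `thermoresp.scoring` | Z-scaling, weighted composite score, ROC/AUC/Youden, weight search, evaluation |
| `thermoresp.pipeline` | video/trace/model I/O, YAML run configuration, end-to-end pipeline |

## CLI

Every stage is a subcommand of `thermoresp`:

```bash
# render a synthetic breathing video + ground truth
thermoresp simulate --duration 45 --fps 30 --breaths 8 --seed 1 \
    --out video.tif --ground-truth gt.json

# denoise, track, and extract features
thermoresp preprocess video.tif clean.tif --fps 30
thermoresp track clean.tif --rois rois.yaml --fps 30 --out-trace trace.csv
thermoresp features trace.csv --label 1 --out features.csv

# fit / apply / evaluate the composite-score classifier
thermoresp search features.csv --iters 1000 --seed 0 --out model.json
thermoresp score model.json features.csv --out scores.csv
thermoresp evaluate scores.csv

# or run everything from one YAML config
thermoresp run config.yaml
```

`rois.yaml` holds the two rectangles (`chest_roi` / `mouth_roi`, each with
`x, y, width, height` in 0-based pixel coordinates, half-open). A pipeline
config lists per-subject videos, labels, and ROIs plus filter/tracker/scoring
settings; see `thermoresp.pipeline.PipelineConfig`.

Supported video formats: multi-page TIFF and `.npy` stacks (pass the frame
rate explicitly), and MP4/AVI when an imageio-ffmpeg backend is installed.

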