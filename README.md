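# swarmscan

Low-cost 2D machine-vision quantification of collective insect swarm
activity: dark, few-pixel bodies on a white arena are segmented by
thresholding, traced with a raster-scan border-following algorithm,
reduced to polygons (Ramer–Douglas–Peucker) with shoelace moments, and
aggregated into timestamped collective-position logs.  A built-in
synthetic swarm generator provides ground truth for every stage, and an
analysis layer produces lateral/vertical displacement spectra,
inactivity gaps and stimulus-presence response reports.

## Modules

| module     | role                                                            |
|------------|-----------------------------------------------------------------|
| `imaging`  | grayscale conversion, the 5 threshold modes, ROI crop, binarize |
| `contours` | border following: outer/hole borders with parent hierarchy      |
| `blobs`    | RDP polygon simplification, moments, size/ROI filtering         |
| `session`  | per-frame records, plain-text session log, CSV export           |
| `synth`    | synthetic swarm renderer with Markov rest/fly motion model      |
| `analysis` | displacement spectra, gap detection, presence-response report   |
| `cli`      | `swarmscan simulate / detect / analyze`                         |

## CLI

Generate a synthetic sequence, detect, analyze:

```sh
swarmscan simulate --seed 1 --frames 100 --out scratch/sim
swarmscan detect --frames scratch/sim/frames --mode 1 --threshold 128 \
    --interval 2.0 --out scratch/session.txt
swarmscan analyze --session scratch/session.txt --min-gap 10 \
    --out scratch/analysis
```

`detect` accepts `--roi X,Y,W,H`, the threshold type `--mode 0..4`
(0 binary, 1 binary inverted, 2 truncate, 3 to-zero, 4 to-zero
inverted; use 1 for dark bodies on a white background so the foreground
becomes 1-pixels), RDP `--epsilon`, and a blob size window
`--min-area/--max-area`.  `analyze` optionally takes a presence
schedule CSV (`label,t_start,t_end`) and writes `spectra.csv`,
`gaps.csv`, `report.csv` and a spectra plot.

Session logs are plain text: three `#`-header lines, then one record
per line (`t=… n=… blobs=x,y;… avg=…`); gap records (no detections)
carry `avg=NA,NA`.

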