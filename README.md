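# cytolink

Multigenerational cell-lineage tracking on labeled segmentation masks.

`cytolink` reconstructs cell lineages from 2D time-lapse microscopy after
segmentation: which cell in frame *t+1* is which cell from frame *t*, where
cells divide (mitosis, 1→2), where they **fuse** (2→1) — an event class most
trackers cannot represent — and where they enter or leave the field of view.
It consumes and emits the Cell Tracking Challenge (CTC) layout (per-frame
16-bit label TIFFs plus a `res_track.txt`/`man_track.txt` lineage file), so
it slots into existing CTC-based pipelines. It is aimed at quantitative
cell biologists and image-analysis developers who need lineage trees —
proliferation, clonal structure, fusion dynamics — rather than positions
alone.

## The model

Tracking is solved as an integer linear program on a spatiotemporal
hypothesis graph. Every detection is a node; candidate events connect
adjacent frames, each with a binary variable x_e and a cost c_e:

    c_e = wt · f_trans(i, j)          transition
          wm + f_mit(i, j, k)         mitosis   (1 parent, 2 daughters)
          wf + f_fus(i, j, k)         fusion    (2 parents, 1 product)

with per-node appearance/disappearance slacks a_v, d_v penalized by wa, wd.
The geometric terms favor small inter-frame motion and size stability for
transitions, and midpoint alignment with area conservation/additivity for
mitosis and fusion. The solver minimizes

    Σ_e c_e x_e + wa Σ_v a_v + wd Σ_v d_v

subject to flow conservation — each node has exactly one selected incoming
event (or appears) and exactly one outgoing event (or disappears) — and
returns the provably optimal lineage for the whole sequence at once.
Candidates are pruned to centroid distances ≤ dmax. A directional heuristic
tracker (bounded-radius bipartite linking plus forward mitosis / backward
fusion detection with distance, area-conservation and similarity criteria)
is included as a baseline, and a Gaussian-process calibration routine tunes
the weight vector against macroscopic biological targets (expected cell,
division and fusion counts) without any ground-truth trajectories.

A synthetic benchmark generator (bounded random walk, scheduled divisions
and proximity-triggered fusions, exact CTC ground truth) and an AOGM-based
TRA scorer complete the loop: generate → track → score. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Generate a 20-frame sequence of 5 cells with 2 scheduled divisions and
1 fusion, track it with the ILP tracker, and compare against the ground
truth:

```sh
cytolink synth --initial 5 --frames 20 --mitosis 2 --fusion 1 \
    --radius 8 --speed 2 --noise 0.5 --field 256 256 \
    --lifespan 5 12 --seed 7 --out gt
cytolink track --masks gt/TRA --method ilp --wt 0.5 --wm 1 --wf 10 --out res
cytolink stats --result res --reference gt --out report.csv
```

The `track` step prints the reconstructed lineage statistics:

```json
{
 "first_frame_cells": 5,
 "last_frame_cells": 6,
 "total_tracks": 10,
 "mitosis_events": 2,
 "fusion_events": 1,
 "mean_track_length": 10.8,
 "median_track_length": 10.0,
 "lifecycle_min": 1,
 "lifecycle_max": 20,
 "lifecycle_mean": 10.8
}
```

10 tracks is exactly the conservation law 5 initial + 2·2 divisions +
1 fusion; both divisions and the fusion were recovered, and `stats` reports
zero deviation on every field. `res/` now contains track-id-relabeled masks,
`res_track.txt` (one `label begin end parent` line per track) and
`lineage.json`, which records both parents of the fusion product — the
standard 4-column format can only hold one.

Composite scores can be computed from CTC component metrics directly:

```sh
$ cytolink metrics --components ct=0.849,bc=0.975,tf=0.957,cca=0.939,lnk=0.997
{
 "bio": 0.93,
 "op_clb": 0.964
}
```

i.e. BIO = 0.25·(CT+BC+TF+CCA) and OP_CLB = 0.5·(LNK+BIO), rounded half-up
to three decimals. A `cytolink sweep --wm-grid ... --wf-grid ...` command
maps lineage statistics (and TRA against a reference) over the
mitosis/fusion penalty plane, and `cytolink calibrate --target
total_tracks=99 --target mitosis_events=41 ...` searches the weight space
for the configuration matching declared biological expectations.

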