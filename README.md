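# meglabel

Anatomical atlas labeling of MEG equivalent current dipoles on a patient's
native MRI.

Clinical MEG reporting requires naming the brain structure under every fitted
equivalent current dipole (ECD) — interictal discharges, somatosensory or
language evoked fields — on the patient's own T1-weighted scan. Doing this by
hand, dipole by dipole, is the slow part of report preparation. `meglabel`
automates it: it normalizes the native T1 into a standard template space,
carries integer-coded anatomical atlases *back* onto the native scan
(reverse normalization), maps each dipole from the MEG head frame through the
MEG–MRI coregistration into T1 voxel space, and reports the atlas label at
every dipole, for every configured atlas — together with the quality-control
and validation statistics needed to trust the result.

It is written for MEG scientists, technologists and researchers who prepare
clinical or research dipole reports and want reproducible, auditable labels
rather than cursor-and-eyeball readings.

## The method in brief

For a dipole with HEAD-frame position $p$, coregistration affine $C$
(HEAD → WORLD, mm), T1 voxel-to-world affine $A$ and native→template
normalization $T$:

* dipole voxel: $v = \mathrm{round}(A^{-1} C\, p)$
* reverse-normalized atlas: $L_\text{native}(x) = L_\text{template}(T x)$,
  sampled nearest-neighbour on the native grid
* label: the lookup-table name for the code $L_\text{native}(v)$; code 0 or a
  code without a table entry means *unlabeled* (typically white matter or CSF
  under a grey-matter atlas).

Dipoles are first filtered by the clinical single-ECD acceptance criteria —
reduced χ² < 2, goodness of fit ≥ 80 %, confidence volume < 1000 mm³, dipole
strength 100–500 nAm (inclusive) — and every dipole is accounted for in
exactly one disposition (accepted / rejected with its first failing
criterion / excluded by judgment).

$T$ can be ingested from external tools (FLIRT-style `.mat`, displacement
field NIfTI, or a canonical text transform) or estimated by the built-in
12-parameter affine registration (normalized cross-correlation, closed-form
moment initialization, rotation grid capture, Powell refinement —
deterministic). Normalization quality is checked by the skull-overlay Dice
between head masks, and labeling accuracy is validated against multi-rater
consensus (k-of-n, default 2-of-3) with explicit concordant/unlabeled counts
and denominators.

See `docs/methods.md` for the full account.

## Worked example

Everything below runs from scratch with no downloaded data: the `synth`
command fabricates a complete subject folder — phantom T1, coregistration,
normalization, a toy 5-region atlas bundle and 20 planted dipoles whose true
region labels are known.

```sh
meglabel synth --out demo --seed 7 --k-regions 5 --n-per-region 2
meglabel label --subject demo --out demo/out
meglabel validate --report demo/out/dipoles.tsv --truth demo/truth.tsv \
                  --atlas toy --out demo/val
meglabel qc --subject demo --out demo/out
```

which prints:

```
wrote synthetic subject with 20 dipoles to demo
labeled 20 accepted dipoles (0 rejected, 0 excluded); report in demo/out
concordant 20/20 (100.0%), unlabeled 0/20 (0.0%)
head-mask Dice: 1.0000 (PASS at 0.85)
QC snapshot in demo/out
```

Reading the output: all 20 dipoles passed the sECD filters (`20 accepted`),
every dipole's atlas label matched its planted ground-truth region
(`concordant 20/20` — with the *true* transforms supplied, accuracy is 100 %
by construction), no dipole fell on an unlabeled voxel, and the
reverse-normalized template head mask overlays the subject's head perfectly
(`Dice 1.0000`), as it must when the saved normalization is exact.

The per-dipole report `demo/out/dipoles.tsv` has one row per dipole:

```
group  dipole_id  disposition  ...  voxel_i voxel_j voxel_k  world_x_mm ...  toy:status  toy:code  toy:label
IED    IED_001    accepted          32      18      29        1.00           labeled     1         region_1
```

To exercise the built-in registration instead of the saved transform, delete
`demo/norm.txt` and rerun `label`: the normalization is then estimated from
the image data (`"normalization": "builtin"` in `summary.json`) and an
estimated-transform file is written alongside the report.

## Library surface

| module | contents |
|---|---|
| `meglabel.geometry` | frame-tagged affines (`FrameTransform`), `Volume`, voxel↔world conversion |
| `meglabel.formats` | `.dip` dipole files, lookup tables, canonical transform/coreg files, FLIRT `.mat` conversion, NIfTI I/O |
| `meglabel.registration` | built-in affine normalization, resampling, displacement fields, Dice QC |
| `meglabel.atlas` | atlas bundles, reverse normalization, label lookup, nearest-labeled fallback, skull outline |
| `meglabel.pipeline` | subject-folder discovery, sECD filtering, dipole→voxel mapping, labeling, accounting |
| `meglabel.validation` | rater consensus, concordance and method-discrepancy statistics |
| `meglabel.synthetic` | seeded phantoms, toy atlases, ground-truth transforms and dipole sets |
| `meglabel.cli` / `meglabel.qc` | `meglabel` command (synth, label, qc, validate, convert-transform), tri-planar snapshots |
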