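# ctradial

Quantitative analysis of **chromosome territory (CT) radial positioning** in
3D confocal nuclei, with companion summaries for per-chromosome
transcriptional deregulation and nuclear-envelope line-scan profiling.  The
package targets 3D-FISH experiments that ask whether a chromosome territory
has moved between the nuclear periphery and the interior — for example in
cells grown on substrates of different stiffness — and ships a
ground-truthed synthetic-data generator so the whole pipeline is testable
without microscopy or sequencing data.

## The statistic

For each territory in a single-nucleus, 3-channel z-stack (blue = DNA
counterstain, green/red = chromosome paints):

* *N* — geometric centre of the segmented nucleus (blue channel),
* *C* — geometric centre of the territory (green or red channel),
* *B* — the point where the ray from *N* through *C* crosses the nuclear
  boundary, found by sub-voxel ray marching on the nucleus mask,
* *R* = |NC|, *Y* = |NB|, and

  **%RD = (R / Y) × 100**

so 0 % is the nuclear centre and 100 % the periphery, independent of
nuclear size and shape along that ray.  All geometry is computed in
physical micrometres (default voxel 0.105 × 0.105 µm in-plane, 0.34 µm
axial; 8-bit channels), so anisotropic sampling is handled by scaling, not
by the geometry code.

Per condition × chromosome, values are pooled into a sample median, a
frequency distribution in 20 %-wide bins, and a two-sided Mann–Whitney U
test against a reference condition.  A *shift table* reports
Δ = median(condition) − median(reference) in percentage points ('+' =
toward the periphery) and, optionally, the within-condition separation
Δ(CTa−CTb) = median_a − median_b.

Two further modules mirror the downstream summaries such a study needs:

* **transcriptome**: from a gene-level table (FPKM per condition, log₂ fold
  change vs reference) — transcribing-gene filter (FPKM > 1), deregulation
  calls (|log₂FC| ≥ 2), per-chromosome % deregulation and enrichment,
  fold-change histograms, and up/down overlap counts between comparisons.
* **envelope**: line-scan intensity profiles across 2D nucleus mid-sections
  rescaled to a common [0, 1] axis, averaged and normalized to the
  reference condition's peripheral intensity, plus a peripheral/interior
  ratio, area-normalized total intensity, and Student's t comparisons.

## Worked example

```python
import ctradial as ct

cfg = ct.demo_config(seed=11)   # 12 nuclei per condition, 2 conditions
ct.run_pipeline(cfg, "demo_out")
```

The demo simulates nuclei in which a gene-poor, normally peripheral
chromosome ("CT18", planted at fractional position 0.66 on glass vs 0.56 on
a soft 2 kPa substrate) and a gene-rich interior chromosome ("CT19", 0.55
vs 0.49) are measured end to end.  `demo_out/shift_table.csv` then reads:

```
condition  median_CT18  delta_CT18  median_CT19  delta_CT19  delta_CT18_CT19
    glass        67.39        0.00        55.05        0.00            12.34
     2kPa        54.02      -13.37        50.22       -4.83             3.80
```

CT18's median %RD drops from 67.4 to 54.0 — a 13-point shift toward the
nuclear interior on the soft substrate (negative Δ), while CT19 moves 5
points; their spatial separation shrinks from 12.3 to 3.8 points.
`demo_out/summaries.csv` carries the per-condition medians, 20 %-bin
frequencies and Mann–Whitney p-values (here p ≈ 4 × 10⁻⁵ for CT18,
p ≈ 0.04 for CT19), and `demo_out/measurements.csv` one row per territory
with N, C, B, R, Y and %RD.

The same stages are available as a CLI:

```sh
ctradial simulate scene --out scene.tif --seed 3 --fractional-position 0.6
ctradial measure scene.tif --out measurements.csv
ctradial summarize measurements.csv --out summaries.csv
ctradial shift-table summaries.csv --reference glass --out shift.csv
ctradial dereg expression.tsv --condition 2kPa --reference glass --out dereg.csv
ctradial run --config config.yaml --out out/
```

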