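# spinecoupling

Quantitative analysis of the coupling between dendritic-spine size and
postsynaptic-density (PSD) size in 3D electron microscopy reconstructions.

The size of a dendritic spine is classically taken as a proxy for the size
of its PSD and hence for synaptic strength. `spinecoupling` is built for
the quantitative side of testing that assumption: it measures spines and
PSD-cores from serial-section contour traces, estimates spine densities
with unbiased-brick stereology, and — its core method — profiles the
*local* Spearman rank correlation between spine volume V (μm³) and PSD
surface area A (μm²) or PSD-core volume V_P (μm³) across the whole
spectrum of spine volumes, to detect volume ranges where the two decouple.
Group statistics (Mann–Whitney, ANCOVA on log₁₀–log₁₀ regressions,
Kruskal–Wallis with Dunn's post-hoc, ratio and relative-change metrics)
compare control and chemically potentiated (cLTP) spine populations.

It is intended for neuroanatomists and image analysts working with
serial-section EM reconstructions (e.g. Reconstruct-style trace data), and
ships a synthetic-population generator so the entire pipeline is testable
without any imaging data.

## The local correlation method

For each spine, sliding windows of *w* = 14…24 spines adjacent in volume
order are centred on it. Each window is resampled 2500 times without
replacement into subsets of *w* − 4 pairs (10–20 elements); a Spearman ρ
and its two-sided p value are computed per subset and averaged over all
subsets and window sizes, giving a local mean ρ and mean p per spine.
Spines with mean p ≥ 0.05 mark volume ranges where V is a poor predictor
of PSD size; maximal contiguous runs of such spines form decoupled bands,
and decoupled-spine counts are compared between groups with a χ² test.

## Worked example

```python
from spinecoupling import (
    SynthConfig, generate_population, LocalCorrParams,
    local_profile, nonsignificant_regions,
)
from spinecoupling.records import split_by_condition

records = generate_population(SynthConfig(seed=0))      # 119 control + 138 cLTP
control, cltp = split_by_condition(records)

profile = local_profile(control, "psd_area", LocalCorrParams(seed=1))
bands = nonsignificant_regions(profile)
print(f"decoupled: {bands.n_decoupled}/{bands.n_total}"
      f" ({100 * bands.fraction:.0f}%)")
for b in bands.bands:
    print(f"band {b['lo']:.3f}-{b['hi']:.3f} um3, {b['n_spines']} spines")
```

prints

```
decoupled: 43/119 (36%)
band 0.037-0.090 um3, 41 spines
band 0.114-0.115 um3, 2 spines
```

i.e. 36% of control spines sit in volume ranges where spine volume does
not significantly predict PSD area, and the dominant decoupled band spans
roughly 0.04–0.09 μm³ — medium-sized spines. Running the same profile on
the potentiated group yields fewer decoupled spines in a narrower band:
potentiation tightens the coupling.

The same analysis is available from the shell:

```bash
spinecoupling simulate --seed 0 --out records.csv
spinecoupling localcorr --records records.csv --condition control \
    --seed 1 --out profile.csv
spinecoupling run --seed 0 --out outdir     # full report bundle
```

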