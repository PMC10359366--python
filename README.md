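# spex

Gene expression prediction from TSS-window epigenomic signal augmented with
protein-mediated spatial chromatin contacts.

Classic expression models summarise epigenomic signal in a fixed window
around a gene's transcription start site (TSS) and see nothing beyond it.
Yet chromatin loops — mediated by cohesin, CTCF or RNAPOL2 and measured by
ChIA-PET or Hi-C — place distal enhancers next to promoters in space. This
package builds per-gene feature tensors that combine both: decay-weighted
local features over the ±20 kb window, plus one spatial column summarising
signal at loop-selected distal regions. It is aimed at computational
genomicists who want to quantify how much 3D contact information adds to a
promoter-window expression model under controlled conditions.

## The model

For gene *g* with TSS *t*, per-track signal is predicted in 200 bp bins over
the 200-bin window centred on *t* (each bin from a 2000 bp context). The
window signal `S ∈ R^{F×200}` is compressed with exponential distance
decays, K scales per side:

    lin[f, k] = Σ_j exp(−d_j / λ_k) · S[f, j]        (upstream / downstream separately)

With F = 2002 tracks and K = 10 this is the classic 400,400 → 40,040
reduction. The spatial column selects contacts at matrix resolution *r*
with one anchor overlapping `[t, t + r)`, count ≥ 2, and the other anchor
entirely outside `[t − 20000, t + 20000)`, then sums predicted signal over
the selected regions:

    sp[f] = Σ_{regions} Σ_{200 bp bins} signal[f, bin]

(falling back to the unweighted window sum when nothing qualifies). The
flattened `F × (2K + 1)` tensors feed a gradient-boosted tree regressor
(squared error) on `ln(expression + 1e−4)`, evaluated on a fully held-out
chromosome (chr8; chrX/Y excluded). Arms with and without the spatial
column are compared by Welch's t-test over repeated training runs, with
Bonferroni correction across experiments, plus a residual analysis
(best-of-factors residuals, mean ± 0.5 SD cutoff, Venn classification).

Any signal source satisfying the predictor contract (interval → F × n_bins
matrix) can stand behind the pipeline; the package ships a synthetic
averaging predictor and a generator that plants loops with known effect
sizes, so every stage runs without downloads. See `docs/methods.md` for the
full model description and design choices.

## Worked example

Generate a small dataset with planted loops, build tensors, train both arms
five times and compare:

```python
import tempfile
from spex import SynthConfig
from spex.pipeline import run_two_arm_experiment

conditions = SynthConfig(
    n_genes=300,
    chrom_lengths={"chr1": 4_000_000, "chr2": 4_000_000, "chr8": 4_000_000},
    loop_distance=(30_000, 200_000),
    seed=1,
)
result = run_two_arm_experiment(conditions, tempfile.mkdtemp(), n_runs=5, base_seed=0)
print(f"fallback rate:      {result['tensor_stats'].fallback_rate:.2f}")
print(f"baseline mean SCC:  {result['mean_baseline_scc']:.3f}")
print(f"spatial mean SCC:   {result['mean_spatial_scc']:.3f}")
print(f"improvement:        {result['improvement']:.3f}")
print(f"Welch p (5 runs) :  {result['welch_p']:.2e}")
```

Output:

    fallback rate:      0.55
    baseline mean SCC:  0.362
    spatial mean SCC:   0.628
    improvement:        0.265
    Welch p (5 runs) :  1.25e-06

About half the genes have a qualifying loop (the rest fall back to their
own window), and the arm that sees the spatial column recovers the planted
spatial effect: its Spearman correlation on the held-out chromosome (chr8)
is 0.27 higher than the baseline's, far beyond the run-to-run spread of
five training seeds per arm.

The same stages are available from the shell:

    spex simulate -c config.yaml
    spex build-tensors -c config.yaml
    spex train-eval -c config.yaml --arm baseline
    spex train-eval -c config.yaml --arm spatial
    spex compare work/metrics_baseline.tsv work/metrics_spatial.tsv -o work

where `config.yaml` holds the paths and the `features` / `model` / `split` /
`runs` / `simulate` sections (unknown keys are rejected). Exit codes: 0 ok,
1 config error, 2 data error.

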