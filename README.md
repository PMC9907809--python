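# satscreen

Analysis and simulation of pooled **site-saturation selection screens**.

`satscreen` is for microbial geneticists who screen saturated mutant
libraries of a gene — every codon of a region substituted, one mutation per
clone — by competitive outgrowth under selection, followed by amplicon
sequencing of the pool before and after. The motivating use case is screens
of the C-terminal signaling domain (residues 50–134) of an outer-membrane
stress-sensor lipoprotein, selected either through the toxicity of its
signaling when mislocalised to the inner membrane, or through
reporter-driven growth on lactose; the machinery is generic to any screen
with the same structure.

## The statistic

For variant *i* in replicate *r*, the read fraction is
*f* = reads / total reads of the sample, and the enrichment score is

```
log2FC_i,r = log2( f_selected / f_control )
```

Variants that fall below the detection threshold after selection are
assigned the relative abundance of 2 reads in that sample (the *dropout
floor*), keeping the score finite; variants never detected in the control
cannot be scored and are flagged instead. Per-replicate scores are averaged
(arithmetic mean; a pooled-count mode is available). Downstream:

* **enriched hits** — missense variants with mean log2FC ≥ cutoff (default 1);
* **depleted hits** — missense variants indistinguishable from the nonsense
  class (at or below the Tukey upper fence, q3 + 1.5·IQR, of the nonsense
  log2FC distribution);
* **codon summaries** — hits grouped per codon, flagging positions where
  proline is the only substitution with a phenotype;
* **cross-screen filtering** — depleted, non-proline variants that were not
  suppressors in the inner-membrane screen (candidates specifically
  defective at the outer membrane);
* **class statistics** — median/quartiles per variant class, one-way ANOVA,
  Bonferroni-adjusted Welch tests against a reference class.

A competitive-growth simulator generates synthetic screens with known
ground truth: per-variant signaling activities, screen-specific
activity→fitness maps, deterministic exponential outgrowth
(n_i(G) = n_i(0)·2^(G·w_i)), an inoculum bottleneck, and multinomial
sequencing sampling. See `docs/methods.md` for the model.

## Worked example

Simulate the toxicity-selection screen (11 generations, triplicate,
10⁶ reads/sample) and score it:

```python
import satscreen as ss

config = ss.SimConfig.for_screen("LOF_IM", seed=7)
data, records = ss.run_screen(config)
hits = ss.call_enriched(records, ss.HitCallParams(enrichment_cutoff=1.0))
codons = ss.codon_summary(hits)
groups = ss.group_stats(records)

print(f"scored variants: {sum(r.log2fc_mean is not None for r in records)}")
for vclass in ("synonymous", "missense", "nonsense"):
    c = groups.classes[vclass]
    print(f"{vclass:>10s}: n={c.n:4d}  median log2FC={c.median:+.2f}  "
          f"IQR=[{c.q1:+.2f}, {c.q3:+.2f}]")
print(f"ANOVA F={groups.anova_F:.1f} (p={groups.anova_p:.3g})")
print(f"missense hits at cutoff 1: {len(hits)} over {len(codons)} codons")
```

prints

```
scored variants: 1777
synonymous: n=  77  median log2FC=-6.48  IQR=[-6.66, -6.22]
  missense: n=1615  median log2FC=-6.39  IQR=[-6.70, -6.03]
  nonsense: n=  85  median log2FC=+3.49  IQR=[+3.45, +3.53]
ANOVA F=375.8 (p=8.36e-137)
missense hits at cutoff 1: 135 over 71 codons
```

Synonymous (wild-type protein) variants are depleted — signaling is toxic
under this selection — while nonsense variants enrich strongly; the 135
missense hits are the simulated loss-of-function tail whose activities were
drawn low. The same pipeline is exposed as a CLI:

```sh
satscreen simulate --screen LOF_IM --seed 7 --out-dir run/
satscreen score --counts run/selective_counts.tsv \
                --counts run/control_counts.tsv --out run/scores.tsv
satscreen call --scores run/scores.tsv --cutoff 1 --out-dir run/calls/
```

Real data enter either as codon-level count TSVs (`satscreen count` builds
them from amplicon FASTQ) or as pre-tabulated amino-acid count tables.

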