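# kdikit

Physicochemical triage of small molecules for CNS drug discovery: Known
Drug Index (KDI) scoring, chemical-space classification, and
descriptor-versus-logBB trend analysis.

## The problem

Whether a small molecule can passively cross the blood–brain barrier is
largely governed by six physicochemical descriptors: molecular weight
(MW, g/mol), the water–octanol partition coefficient (log *p*),
hydrogen-bond donor and acceptor counts (HD, HA), polar surface area
(PSA, Å²), and rotatable-bond count (RB). Medicinal chemists triage
candidate compounds by (a) scoring how drug-like the descriptor profile
is, (b) locating it within nested chemical-space regions (lead-like ⊂
drug-like ⊂ Known Drug Space), and (c) checking the profile against the
empirical trends linking each descriptor to logBB, the log10 ratio of
brain to blood concentration at steady state.

## The model

The KDI scores each descriptor *d* with a Gaussian desirability function
fitted to the descriptor distribution of drugs in clinical use
(Eurtivong & Reynisson, *Mol. Inform.* 2019):

    I_d = exp( −(x_d − μ_d)² / (2 σ_d²) )  ∈ (0, 1]

with shipped parameters (μ, σ): MW (371.76, 112.76), log p (2.82, 2.21),
HD (1.88, 1.7), HA (5.72, 2.86), RB (4.44, 3.55), PSA (79.4, 54.16).
The six indexes aggregate two ways:

    KDI_2a = Σ I_d   (theoretical maximum 6)
    KDI_2b = Π I_d   (theoretical maximum 1)

KDI_2b is the unforgiving variant: one poor descriptor collapses the
product. Chemical-space classification reports the innermost region
containing each descriptor (bounds inclusive) and the compound overall.
Trend analysis computes, per descriptor over complete cases, Pearson's r
(primary), Spearman's ρ, and the least-squares line logBB = a·x + b,
calling a direction ("facilitates"/"impedes") when |r| exceeds a
configurable threshold (default 0.1).

Because curated logBB collections are not redistributable, the package
includes a seeded synthetic generator that emulates their statistical
structure (known-drug descriptor marginals; logBB linear in standardized
descriptors with lipophilicity facilitating and polarity impeding).

## Worked example

```sh
python examples/score_published_table.py
```

```
compound    KDI_2a  KDI_2b
MAC-197       4.06    0.07
MAC-198       3.89    0.04
Myrtenal      3.37    0.01
```

The two adamantane–myrtenal conjugates score near the known-drug average
(≈4), meaning a descriptor balance typical of marketed drugs; the parent
monoterpene scores lower, mostly through its small MW. The trend example
(`python examples/logbb_trends.py`) prints one direction sentence per
descriptor, e.g.

```
Higher logP facilitates barrier permeability (Pearson r = +0.550, Spearman rho = +0.517, n = 208).
Higher PSA impedes barrier permeability (Pearson r = -0.492, Spearman rho = -0.430, n = 208).
```

— the classic BBB pattern: lipophilicity helps brain entry, polarity
hurts it. See `examples/` for chemical-space classification and the
drug-like KDI background distribution, and `kdikit --help` for the batch
CLI (`score`, `classify`, `trends`, `simulate`).

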