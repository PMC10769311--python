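# bsbind

Mechanistic mass-action modelling of bivalent antibodies binding the
interleukin-6 and interleukin-8 receptors (IL-6R, IL-8R) on cells.

IL-6 and IL-8 signalling synergistically drives cancer metastasis, and both
receptors can be blocked with antibodies: the monospecific antibodies
tocilizumab (two anti-IL-6R arms) and 10H2 (two anti-IL-8R arms), and the
bispecific antibody BS1 (one arm of each). Because all three are bivalent,
their pharmacology is governed not only by per-arm affinity but by avidity —
a surface-tethered antibody cross-links a second receptor far faster than a
free antibody binds its first. `bsbind` is for quantitative pharmacologists
and modellers who want to simulate, calibrate, and interrogate this system:
which complexes form (binary Ab·R vs ternary R·Ab·R), at which doses and
receptor densities, and how bispecific binding differs from a combination of
monospecifics.

## The model

Binding proceeds by reversible two-step mass action. For a bispecific
antibody on a cell expressing both receptors:

    Ab + R1  ⇌  Ab·R1          (kon,R1, koff,R1)
    Ab + R2  ⇌  Ab·R2          (kon,R2, koff,R2)
    Ab·R2 + R1  ⇌  R1·Ab·R2    (kon,R1*, koff,R1*)
    Ab·R1 + R2  ⇌  R1·Ab·R2    (kon,R2*, koff,R2*)

Starred constants are the cross-linking (second-arm) steps. These four
reactions close a thermodynamic cycle, so detailed balance forces the
product of their equilibrium constants to one; together with the assumption
that dissociation is identical for first- and second-step unbinding
(koff,R = koff,R*), the whole three-antibody system reduces to five free
parameters — kon,6R, kon,8R, kon,6R*, koff,6R, koff,8R — with kon,8R*
derived from the cycle. The ratio

    χ = kon,R* / (α · kon,R)

is the cross-arm binding efficiency (α = 8.3×10⁻⁷ nM per receptor/cell
converts between solution and surface units for 10⁵ cells in 200 µL).
Free antibody is tracked in nM and surface species in receptors/cell.

The package ships the rate constants calibrated against flow-cytometry
binding assays on receptor-transduced HEK 293T cells
(`bsbind.REFERENCE_RATES`), plus the measured receptor expression of the
three cell lines (`bsbind.HEK293T_LINES`).

Modules:

- `bsbind.kinetics` — rate-constant algebra (cycle completion, unit
  conversion, equilibrium constants) and reaction-network assembly for any
  antibody or combination on any cell line.
- `bsbind.protocol` — stiff ODE simulation of the assay timeline
  (association, washout, detection), bound-receptor/bound-antibody
  summaries, AUC, dose × receptor sweeps, bispecific-vs-combination
  comparison.
- `bsbind.fitting` — MFI normalization schemes and multi-start
  (Latin-hypercube) bounded least-squares calibration of the five free
  parameters in log10 space.
- `bsbind.sensitivity` — local (+10%, AUC-based) and global (two-decade,
  occupancy-based) univariate sensitivity analyses.
- `bsbind.synthetic` — flow-cytometry-like synthetic dose-response datasets
  from known ground-truth parameters, for calibration testing.
- `bsbind.cli` — the `bsbind` command with `simulate`, `fit`, `sweep`,
  `sensitivity` and `generate` subcommands.

## Worked example

```python
import bsbind as bs

# Equilibrium constants derived from the calibrated rates
eq = bs.equilibrium_table(bs.REFERENCE_RATES)
for name, value in eq.as_dict().items():
    print(f"{name:12s} {value:.3g}")

# BS1 at 100 nM on the double-positive cell line: 2 h binding,
# washout, then a 15 min detection window
network = bs.build_network(bs.BS1, "IL6R+IL8R+")
schedule = bs.DoseSchedule(doses_nM={"BS1": 100.0})
tc = bs.simulate(network, bs.REFERENCE_RATES, schedule)
s = bs.summarize(tc)
print(f"binary complexes : {s.bound_binary:,.0f} receptors/cell")
print(f"ternary complexes: {s.bound_ternary:,.0f} receptors/cell")
print(f"bound antibody   : {s.bound_antibody_signal:,.0f} antibodies/cell")
print(f"IL-6R occupancy  : {s.occupancy['IL6R']:.3f}")
print(f"IL-8R occupancy  : {s.occupancy['IL8R']:.3f}")
```

prints

```
KD_6R        9.48
KD_8R        7.07
KD_6R_star   0.000574
KD_8R_star   0.000428
chi          1.65e+04
binary complexes : 277,082 receptors/cell
ternary complexes: 620,433 receptors/cell
bound antibody   : 587,298 antibodies/cell
IL-6R occupancy  : 0.997
IL-8R occupancy  : 0.942
```

The first-step dissociation constants (~9.5 and ~7.1 nM) are ordinary
antibody affinities; the sub-picomolar cross-linking constants and
χ ≈ 1.6×10⁴ quantify the avidity of the second-arm step. In the simulated
assay most receptor ends up in ternary complexes: nearly all of the scarcer
IL-6R is occupied, and each bound antibody bridges, on average, more than
one receptor. Ternary complexes survive the washout — they even increase
slightly as binary complexes dissociate and free receptor becomes available
for cross-linking.

The same machinery drives the package's other analyses: dose–response
sweeps showing the bell-shaped ("autoinhibition") ternary curve at high
receptor expression, monovalent-restricted simulations (cross-link rates
zeroed), and the comparison showing that BS1 out-occupies a 1:1
tocilizumab+10H2 combination on the scarcer receptor when expression is
imbalanced.

A shell session with the CLI:

```sh
bsbind --out-dir out --seed 7 generate          # synthetic assay dataset
bsbind --out-dir out --seed 7 fit out/synthetic_data.csv --n-starts 50
bsbind --out-dir out sensitivity --mode local
```

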