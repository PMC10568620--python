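# tkiswitch

Deterministic modelling of drug-resistance evolution in EGFR-mutant
non-small-cell lung cancer (NSCLC) under EGFR tyrosine-kinase-inhibitor
(TKI) therapy, and of the scheduling question it raises: **which drug
first, and when to switch?**

The package is aimed at computational oncologists and modellers who want a
tested, exactly solvable baseline for sequential-therapy questions: it
simulates tumor burden under erlotinib-first, osimertinib-first and
combination schedules, locates the optimal drug-switch day, and maps which
strategy wins as a function of the tumor's initial resistant composition.

## The model

Four genotypes compete under two drugs:

| type | genotype | DrugA (erlotinib-class) | DrugB (osimertinib) |
|------|----------|------------------------|---------------------|
| W | driver mutation only | sensitive | sensitive |
| X | + T790M | resistant | sensitive |
| Y | + C797S | sensitive | resistant |
| Z | + T790M + C797S | resistant | resistant |

Each genotype grows exponentially at a regimen-dependent net rate and
mutates irreversibly toward resistance, giving a triangular linear system
under any constant regimen:

```
dw/dt = a w
dx/dt = g w + b x
dy/dt = h w + c y
dz/dt = k w + p x + q y + f z
```

with per-day growth rates `a, b, c, f` (negative under an effective drug)
and mutation rates `g, h, k, p, q` (1e-7/day at the defaults).  The system
is solved **exactly** by a divided-difference cascade (see
`docs/methods.md`), so multi-phase schedules accumulate no integration
error; an adaptive DOP853 integration is kept as an independent oracle.
The bundled rate table covers three regimens: A (erlotinib), B
(osimertinib) and C (both drugs combined).

## Worked example

```python
import tkiswitch as tk

table = tk.default_parameter_table()          # regimens A, B, C
initial = tk.standard_initial_state()         # 1e9 cells; X0=Y0=1e4, Z0=10

for strategy, schedule in tk.standard_schedules().items():
    traj = tk.simulate_schedule(initial, schedule, table, output_step=1)
    print(strategy, f"{traj.final_total:.3g}", tk.recurrence_time(traj))
```

prints

```
A-first 2.12e+12 254.82602456743118
B-first 1.09e+12 478.0415189431162
C 4.2e+12 620.7301115003279
```

i.e. starting from a just-detectable 1e9-cell tumor, erlotinib-first
(switching to osimertinib at day 307) ends the 1000-day horizon at
2.12×10¹² cells and regrows to baseline by day ~255; osimertinib-first
(switch at day 567) ends lower (1.09×10¹²) and recurs later (~day 478);
the combination delays recurrence the longest (~day 621) but ends highest
(4.2×10¹²) because the doubly resistant Type-Z clone grows unopposed from
the start.

The `examples/` directory holds one short narrative script per
capability: sequential-therapy time courses, switch-day optimisation
(`sweep_switch_time`), the therapy-selection map over initial resistant
fractions (`build_selection_map`), and randomized scenario generation
with closed-form vs ODE cross-checking.  The `tkiswitch` command exposes
the same operations from a shell (`tkiswitch run-all` reproduces every
simulation, experiment CSV and figure in one go).

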