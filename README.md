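# is3sim

**Predicting the synaptic input regimes of hippocampal IS3 interneurons.**

IS3 cells (interneuron-specific type 3; VIP+/CR+ cells of hippocampal CA1
that inhibit other interneurons) have never been recorded intracellularly
*in vivo*. `is3sim` is a simulation package for asking what their in-vivo
input should look like anyway: a reduced multi-compartment conductance-based
IS3 model is bombarded with parameterized excitatory and inhibitory spike
trains, every output is scored for being "in-vivo-like", and the input
parameter space is swept, pooled, and probed with voltage-clamp and
theta-rhythm protocols.

It is aimed at computational neuroscientists who want a self-contained,
testable re-implementation of this workflow - the compartmental solver, the
synapse bank, the input generator, the metrics, and the experiment
protocols are all importable pieces.

## The model and metrics in brief

A 221-compartment IS3-like morphology (soma, axon initial segment, ten
tapered dendrites spanning 425 um) carries transient/persistent Na and
A-type/delayed-rectifier K conductances in two variants - AType+ (A-current
in soma and proximal dendrites) and AType- (A-current somatic only) - plus
a calibrated leak and somatic Gaussian noise. The cable equation is stepped
implicitly (backward Euler, Hines solve, dt = 0.025 ms) with
double-exponential synapses: 1530 excitatory and 344 inhibitory slots whose
weights grow linearly with distance and whose time constants are fixed per
class.

An input scenario is a point (f_E, f_I, N_E, N_I, k_E, k_I): presynaptic
rates, active synapse counts, and common-input group sizes (k synapses
sharing one train). Each 10 s simulation is summarized over its last 9 s by
the mean and SD of the subthreshold voltage, the inter-spike-interval
coefficient of variation, and the mean spike amplitude, combined as

    IVL = (V̄m > -66.7 mV) + (σVm > 2.2 mV) + (ISICV > 0.8) − 4·(S̄A < 40 mV)

IVL = 3 marks an in-vivo-like state, 0 non-in-vivo-like, negative values
depolarization block. Excitation/inhibition balance is tracked by
EI₁ = 0.5(N_E/N_E,max + f_E/f_E,max − N_I/N_I,max − f_I/f_I,max) ∈ [−1, 1]
and EI₂ = f_E·N_E − f_I·N_I. Conductance-isolation (ideal somatic clamp,
G = I/(V_hold − E_R)) and deterministic 8 Hz theta-input protocols probe
the balance and rhythm sensitivity of chosen scenarios. See
`docs/methods.md` for the full account.

## Worked example

```python
from is3sim import CellModel, InputScenario, input_resistance

# build the fixture morphology and calibrate leak + noise (about a minute)
cell = CellModel.calibrated("AType+")
print(f"Ri = {input_resistance(cell.model).r_in:.2f} MOhm")

# one in-vivo-like scenario: 144 excitatory synapses at 5 Hz, 40 inhibitory
# at 50 Hz, common inputs in groups of 9 (E) and 4 (I)
res = cell.run_scenario(InputScenario(5, 50, 144, 40, k_e=9, k_i=4, seed=1338891006))
m = res.measurements
print(f"mean Vm = {m.mean_sub_vm:.1f} mV, sigma = {m.sigma_sub_vm:.2f} mV, "
      f"ISICV = {m.isi_cv:.2f}, amplitude = {m.mean_spike_amp:.1f} mV")
print(f"IVL metric = {res.ivl.ivl_metric} ({res.ivl.state}), "
      f"rate = {res.mean_rate_hz:.1f} Hz")
```

prints

```
Ri = 388.71 MOhm
mean Vm = -64.3 mV, sigma = 4.33 mV, ISICV = 1.02, amplitude = 91.9 mV
IVL metric = 3 (IVL), rate = 2.3 Hz
```

i.e. the calibrated cell hits its measured input resistance, and this
low-input, inhibition-balanced scenario depolarizes the cell several mV,
raises its voltage fluctuations well past the 2.2 mV criterion, and makes
it fire sparsely but Poisson-irregularly (ISICV ≈ 1) with full-height
spikes - an in-vivo-like state.

The same machinery is scriptable from the shell:

```bash
is3sim fixtures                      # write the SWC morphology + synapse bank CSV
is3sim simulate config.yml           # one scenario -> trace.csv + measurements.json
is3sim sweep config.yml --limit 200  # coarsened grid sweep -> records CSV
is3sim pools sweep_records.csv       # per-pool IVL/NIVL/DB counts
is3sim plot-cbdr sweep_records.csv   # 4-D grid nested into a 2-D image + sidecar
is3sim clamp config.yml              # isolated g_E/g_I traces and E/I ratio
is3sim theta config.yml              # PSD at 8 Hz before/after theta inputs
```

where `config.yml` holds the variant, the two fitted calibration values
(omit them to recalibrate), and the scenario parameters.

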