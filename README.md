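# petblock

Kinetic quantification for TSPO PET blocking studies with arterial input:
two-tissue compartment modelling of [11C]PBR28, occupancy (Lassen) plot
estimation of drug occupancy and non-displaceable binding, and the SIME
blocking-free V\_ND estimator — plus a synthetic-data generator with full
ground truth so every stage can be validated without access to raw scans.

## The problem

The 18-kDa translocator protein (TSPO) is upregulated in activated
microglia, and TSPO PET radioligands such as [11C]PBR28 are used to image
neuroinflammation. [11C]PBR28 has no reference region: its total
distribution volume V\_T mixes specific binding (V\_S) with non-displaceable
uptake (V\_ND). Whether group differences in V\_T reflect biology or V\_ND
differences can only be settled by pharmacological blocking — scanning each
subject before and after a dose of a TSPO-selective drug (XBD173/emapunil)
and asking how much of the signal was displaced.

`petblock` implements the full quantification chain such a study needs:

1. **Blood** (`petblock.blood`): discrete arterial samples are turned into a
   metabolite-corrected plasma input function
   C\_p(t) = C\_b(t−Δ)·POB(t−Δ)·PPf(t−Δ), with a piecewise multi-exponential
   whole-blood model, extended-Hill fits of the plasma-over-blood ratio
   (POB) and parent plasma fraction PPf(t) = 1 − a·tᵇ/(tᵇ+c), continuous-line
   calibration, and a grid-searched blood-to-brain delay Δ.
2. **Kinetics** (`petblock.tcm`): weighted nonlinear least-squares fitting of
   the standard 2TCM (K1, k2, k3, k4, V\_B) and the 2TCM1K variant with an
   irreversible vascular compartment (rate K\_b from whole blood), with
   V\_T = (K1/k2)(1 + k3/k4), delta-method CVs, and exclusion of
   non-physiological fits (V\_T > 10 mL/cm³ or CV > 50%).
3. **Occupancy plot** (`petblock.occupancy`): from paired baseline/blocking
   V\_T across regions, V\_T,base − V\_T,block = Occ·(V\_T,base − V\_ND);
   the slope is the occupancy, the x-intercept is V\_ND. Fits are per subject
   (bootstrap CIs) or population-constrained to one shared V\_ND
   (profile-likelihood CI).
4. **SIME** (`petblock.sime`): a blocking-free estimator that pins
   K1/k2 to a candidate V\_ND in every region, sweeps a 0.01–5 mL/cm³ grid
   (0.01 steps), and takes the pooled-RSS minimiser from a single baseline
   scan.
5. **Reports** (`petblock.report`): regional percent-V\_T-change tables,
   SIME-vs-Lassen comparisons with paired t-tests, and an end-to-end
   pipeline runner.
6. **Synthetic data** (`petblock.synth`): cohorts whose regional TACs,
   blood curves and noise reproduce the structure of a real 26-frame,
   90-min blocking study, with every curve traceable to its generating
   parameters.

## Worked example

Estimate occupancy and V\_ND for a simulated 7-subject cohort
(`examples/04_occupancy_plot.py`):

```text
subject   occupancy   V_ND  [95% CI]
sub-01          77%   2.11  [1.88, 2.41] (truth occ 73%)
sub-02          69%   1.96  [1.68, 2.40] (truth occ 68%)
...
population-constrained V_ND: 2.05 mL/cm3 (95% profile CI 1.95-2.15; truth 1.99)
occupancy across subjects: 74% +/- 3%
```

Each line is one subject's occupancy plot: the slope (percent of TSPO sites
blocked) and the x-intercept (V\_ND, the non-displaceable distribution
volume) with a bootstrap CI over regions. The population-constrained fit
shares one V\_ND across subjects and recovers the generating value
1.99 mL/cm³ within its profile-likelihood CI.

Reproducing the published summary statistics from the study's printed
tables (`examples/06_study_tables.py`):

```text
SIME V_ND: 1.16 +/- 0.28 mL/cm3 (population SD)
SIME vs Lassen: -45.4% +/- 21.7%
paired t(6) = -2.52, p = 0.045
```

The other examples cover cohort simulation, input-function fitting, a
single kinetic fit, and the SIME grid profile. A thin CLI mirrors the
pipeline stages on a TSV/JSON file tree:

```bash
petblock simulate --seed 3 --out cohort/
petblock fit-blood --blood cohort/sub-01/baseline/blood.tsv \
    --continuous cohort/sub-01/baseline/blood_continuous.tsv \
    --tac cohort/sub-01/baseline/tac_whole_brain.tsv --out input.json
petblock fit-tcm --model 2tcm --tac-dir cohort/sub-01/baseline \
    --input input.json --out fits.csv
petblock sime --tac-dir cohort/sub-01/baseline --input input.json --out sime.json
petblock run-all --seed 3 --out study/
```

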