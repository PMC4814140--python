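# aqpscope

Analysis toolbox for aquaporin (AQP) channel selectivity, built around the
biology of the plant vacuolar aquaammoniaporin AtTIP2;1 and its comparison
with water-specific channels such as human AQP1.

Aquaporins are homotetrameric membrane channels; each monomer conducts water
(and in some isoforms other small neutral solutes) through a narrow pore whose
substrate profile is set by the residues lining its non-cytosolic end. In
TIP2-type channels the classical four-residue aromatic/arginine selectivity
filter is extended by a fifth residue contributed by loop C, giving five
positions ordered **H2ᴾ, LCᴾ, H5ᴾ, LEᴾ, HEᴾ** (helix 2, loop C, helix 5, the
loop E backbone carbonyl, and the near-universal helix E arginine). A
histidine at H2ᴾ with an aromatic residue at LCᴾ and a small/hydrophobic
residue at H5ᴾ marks an ammonia-permeable filter; a histidine at H5ᴾ paired
with an LCᴾ asparagine marks a water-specific one.

`aqpscope` packages the quantitative analyses around that biology:

- **`structure_io`** — PDB/mmCIF/FASTA I/O with a documented element→vdW
  radius table, atom selection, and Kabsch superposition.
- **`pore_profiler`** — sphere-fitting pore-radius profiles along a channel
  axis: at each axial position z the largest probe sphere not overlapping any
  atom, `r(z) = max_c min_i (|c − xᵢ| − vdwᵢ)`, found by seeded multi-start
  search; profile alignment and minimum-diameter queries.
- **`filter_annotator`** — NPA-motif anchoring, the five filter positions from
  sequence and/or structure, five-letter filter codes, rule-based specificity
  calls, and the LEᴾ-carbonyl spatial group (group II when pinned by an LCᴾ
  asparagine hydrogen bond).
- **`traj_observables`** — permeation-event counting, single-channel osmotic
  permeability `p_f = v_w·D_n` from the collective water coordinate n(t),
  hydrogen-bond profiles along the pore, density grids, χ₁ rotamer
  populations, and WHAM reconstruction of umbrella-sampled free-energy
  profiles with barrier heights.
- **`kinetics`** — stopped-flow single-exponential fits `A(1 − e^{−kt}) + c`,
  rate-versus-gradient regression, Henderson–Hasselbalch NH₃ gradients, and
  the yeast-assay specificity table: empty-vector background correction
  (clipped at zero), ammonia/water ratios with propagated errors, and
  classification against a reference channel.
- **`synthetic_data`** — deterministic generators with known ground truth
  (toy channels, Brownian pore trajectories, umbrella windows, noisy traces)
  plus the packaged construct-panel fixtures.
- **`cli`** — the `aqpscope` command wiring it all together.

## Worked example

Build the specificity table for the construct panel (AtTIP2;1, HsAQP1 and
HsAQP1 mutants carrying TIP2-like filter substitutions):

```sh
python - <<'EOF'
from aqpscope.synthetic_data import table2_rates
table2_rates().to_csv("rates.csv", index=False)
EOF
aqpscope kinetics table --rates rates.csv \
    --background "Empty vector" --reference "AtTIP2;1" --out table.tsv
```

`table.tsv` (abridged):

```
construct                corrected_ammonia  corrected_water  ratio  call
AtTIP2;1                 32.4               10.2             3.2    AtTIP2;1-like
HsAQP1 wt                0.0                33.2             0.0    Water
H180I                    4.8                0.32             15.0   Ammonia
F56H N127H H180I         3.2                0.08             40.0   Ammonia
F56H N127H H180I C189G   5.7                1.95             2.9    AtTIP2;1-like
```

Reading: ammonia rates are in 10⁻² s⁻¹, water rates in s⁻¹, and the ratio
(ammonia/water × 10⁻²) measures relative substrate specificity independent of
expression level. After subtracting the empty-vector background, wild-type
HsAQP1 conducts only water (ratio 0); the H5ᴾ mutant H180I becomes
ammonia-biased (ratio 15) but loses most water transport; only the quadruple
mutant (all four deviating filter positions swapped to the TIP2;1 residues)
reproduces the AtTIP2;1-like balance of ~3% ammonia-to-water rate.

Classify filter codes directly:

```sh
$ aqpscope classify HHIGR FNHCR
HHIGR   aquaammoniaporin   H2P histidine, aromatic LCP and open H5P: ammonia-permeable filter
FNHCR   water_specific     H5P histidine with LCP asparagine: canonical water-specific filter
```

Other entry points: `aqpscope profile` (pore-radius CSV from a PDB),
`aqpscope annotate` (filter TSV from FASTA, optionally reconciled with a
structure), `aqpscope traj pf|events|hbonds|density|chi1|wham`, and
`aqpscope simulate cylinder|brownian|umbrella|trace` to generate inputs with
recorded ground truth.

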