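# wrapkit

Quantitative analysis of DNA wrapping by tetrameric bacterial histones.

Bacterial histones of the face-to-face (FtF) subfamily assemble into stable
homotetramers whose perimeter carries a continuous band of DNA-binding
surface.  Whether such a tetramer *bridges* two separate DNA duplexes across
opposite faces or is *wrapped* by a single ~60-bp segment is decided
quantitatively: by counting protein–DNA heavy-atom contacts per binding site
along MD trajectories, by measuring wrap coverage in base pairs, by
integrating the work of steered unwrapping, and by sizing the DNA footprint
that the protein protects from nuclease digestion.  `wrapkit` implements
that entire analysis chain as a tested, reusable library for structural
biologists and simulators working on histone–DNA and other protein–DNA
wrapping problems.

## What it computes

* **Structure plumbing** (`wrapkit.structio`) — PDB/mmCIF/FASTA I/O through
  gemmi/Biopython, a compact atom-selection language with nucleic-acid and
  protein atom classes, and crystallographic symmetry expansion: all
  space-group operators plus lattice translations are applied and mates
  within a radius of a seed selection are kept, which rebuilds biological
  tetramers and the continuous DNA helices of a crystal lattice from an
  asymmetric unit.
* **Model building** (`wrapkit.builder`) — idealized B-DNA from rigid
  nucleotide templates laid along a straight axis or circular arc with per-
  step rise *h* and twist *Ω* (fibre-B defaults *h* = 3.4 Å, *Ω* = 36°/bp),
  and assembly of wrapping (tetramer + one 67-bp duplex) or bridging
  (tetramer + two 32-bp duplexes) starting models from crystal-derived
  interface templates, with clash control and exact rise/twist round-trip.
* **Contact analytics** (`wrapkit.contacts`) — binding contacts defined as
  heavy-atom pairs within 4 Å (inclusive), decomposed over the four
  canonical binding sites of an FtF tetramer (two β-bridge A-sites, two
  paired-end-of-helices B-sites), per residue, and by moiety
  (phosphate/sugar/base × backbone/sidechain); binding fluctuation
  δ_t = c_t − c̄; centered moving-average smoothing; hydrogen-bond and
  salt-bridge occupancy.
* **Geometry** (`wrapkit.geometry`) — Kabsch superposition, DNA-backbone
  RMSD series after protein fitting, tetramer planarity dihedral, helix
  crossing angles, wrap coverage (bp in contact, longest run, angular
  coverage), and free-energy landscapes F = −kT ln(P/P_max) over two
  collective variables.
* **Steered unwrapping** (`wrapkit.unwrap`) — cumulative work
  W(ξ) = ∫F dξ, barrier detection with attribution to the binding site
  whose contacts drop across the barrier, site release order, and a
  cutoff-based per-residue Coulomb + Lennard-Jones interaction-energy
  decomposition.
* **Assay quantitation** (`wrapkit.assays`) — average-mass arithmetic for
  SEC-MALS stoichiometry, Shine–Dalgarno scans to rank start codons,
  densitometric sizing of nuclease-ladder lanes against a marker, 4-parameter
  logistic fits of tethered-particle-motion (TPM) compaction curves, and
  depletion-aware 1:1 / Hill binding-isotherm fits with AIC model selection.
* **Synthetic fixtures** (`wrapkit.synthetic`) — seeded generators for toy
  wrapping/bridging ensembles with planted site engagement, staircase-work
  pulling series, gel lanes from a known migration model, and titration
  curves, each with serialized ground truth, so the full pipeline is
  testable without any downloads.

## Worked example

Classify a wrapping-mode ensemble, find its unwrapping barriers, and check
the tetramer's stoichiometric mass:

```python
from wrapkit import assays, contacts, synthetic, unwrap
from wrapkit.refdata import hlp_like_sequence

traj, truth = synthetic.gen_toy_complex(
    synthetic.ToySpec(mode="wrapping", n_frames=60, jitter=0.3, seed=1))
sites = contacts.define_canonical_sites(traj.topology)
series = contacts.contact_series(traj, sites, traj.selection_masks["dna"])
print(series.site_summary().round(1))
print(f"total contacts: {series.mean:.1f} ± {series.sd:.1f}")

pull, site_contacts, _ = synthetic.gen_smd_series(noise=1.0, seed=1)
profile = unwrap.work_profile(pull)
for b in unwrap.detect_barriers(profile, min_height=100.0,
                                site_contact_series=site_contacts):
    print(f"barrier at ξ = {b.xi_peak:.0f} Å: {b.height:.0f} kJ/mol ({b.site})")

mass = assays.protein_mass(hlp_like_sequence())
print(f"histone mass: {mass.mass:.1f} Da ({mass.kda} kDa)")
```

prints

```
          mean   sd
site
A-site 1  22.9  3.7
A-site 2  27.8  4.6
B-site 1  25.3  3.7
B-site 2  20.2  3.6
total contacts: 96.2 ± 7.6
barrier at ξ = 15 Å: 498 kJ/mol (B-site 2)
barrier at ξ = 40 Å: 401 kJ/mol (A-site 2)
histone mass: 7121.2 Da (7.1 kDa)
```

All four binding sites carry contacts — the wrapped signature (a bridging
ensemble leaves the A-sites at zero).  The work profile resolves the two
planted unwrapping barriers, attributes the first to B-site 2, and the
63-residue histone weighs in at 7.1 kDa, so a tetramer with two 30-bp
duplexes (≈ 65 kDa) matches a ~69 kDa solution mass within the usual
SEC-MALS accuracy.

A thin CLI mirrors the main operations:

```bash
wrapkit simulate --mode bridging --seed 7 fixtures/
wrapkit contacts fixtures/topology.pdb fixtures/frames.txt contacts.tsv
wrapkit expand --radius 20 --seed "chain A" in.cif out.pdb
wrapkit mass MSKKEQ...  # or a FASTA file
```

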