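# Methods

This note records the model as implemented, the defaults and why they were
chosen, and what the synthetic validation does and does not demonstrate.

## Body-bar constraint networks

Atoms are 6-DOF rigid bodies; interactions are multi-bar edges:

| constraint class    | bars | component entropy (units of R) |
|---------------------|------|-------------------------------|
| covalent, rotatable | 5    | 0                             |
| covalent, locked    | 6    | 0                             |
| hydrogen bond       | 5    | γ_t ∈ [γ_min, γ_max]          |
| native torsion      | +1   | δ_nat                         |
| disordered torsion  | +1 (probe) | δ_dis                   |

A covalent bond is rotatable iff it is a single bond, not a peptide/amide
bond, not in a ring (detected as a non-bridge of the covalent graph, which
also makes proline's φ non-rotatable), and each endpoint keeps at least one
further heavy-atom neighbor.  Rotatable backbone bonds are labeled φ (N–CA)
and ψ (CA–C); everything else is χ.

**H-bond detection.** Donor–acceptor heavy-atom distance ≤ 3.5 Å,
hydrogen–acceptor distance ≤ 2.5 Å and D–H–A angle ≥ 100° when hydrogens
are present; a documented heavy-atom-only fallback exists behind an
explicit flag.  Charged donor/acceptor pairs (Lys/Arg/His vs Asp/Glu/OXT)
are flagged salt bridges and treated as H-bonds.  The energy is a smooth
empirical well, −8 kcal/mol at ideal geometry decaying to 0 at the cutoffs.
Only the *ordering* of H-bond energies matters downstream (it fixes the
preferential placement order), so the well shape is a configurable
surrogate, not a claim about the true potential.

**Component entropies.** γ_t is an affine map of the H-bond energy onto
[0.05, 1.2]: strongest bond → lowest entropy.  The range is chosen so that
γ_max < δ_nat < δ_dis, keeping the class ordering of the preferential
placement stable across the parameter ranges explored during fitting.

## Pebble game

The (6,6) body-bar pebble game: each body holds six pebbles, a bar between
u and v is independent iff seven pebbles can be gathered on {u, v} (pebble
searches with path reversal).  Failed searches delineate the stressed
(over-constrained) regions; overlapping stressed regions are merged.
Rigid clusters are the transitive closure of pairwise-rigid *adjacent*
bodies (pair test: can seven pebbles be gathered on the pair); the
rank-oracle cross-check uses the identical closure, so the comparison
isolates the combinatorial algorithm against independent linear algebra.
Internal DOFs are F = (free pebbles) − 6·(connected components).

**Per-constraint independence (q).** q is stored as the *fraction* of a
constraint's bars that absorb pebbles.  For single-bar torsion constraints
this is the usual binary flag.  For multi-bar constraints the fractional
form is what makes the entropy of the independent set a minimum-weight
matroid basis under entropy-ascending placement — i.e. it makes the
"lowest possible upper bound" property of preferential ordering an exact
theorem rather than an approximation, and the property is tested as such
(zero violations over thousands of random orders).

**Region decomposition.** The mechanical decomposition (clusters, hinges,
regions) is computed on the network *without* disordered-torsion probes;
the probes are then placed last, in entropy order, and their independence
counts the internal DOFs A per flexible region (A ≤ H by construction).
Ties in the placement order break by ascending energy, then constraint
index, so q-values are reproducible.

## DCM thermodynamics

Macrostates (N_hb, N_nat) are sampled uniformly: each topology draws N_hb
candidate H-bonds and N_nat native torsions without replacement (all
networks equal-weighted within a macrostate).  Defaults: 200 topologies per
macrostate (fewer suffice for stable q̄s; the validation studies use 16–50
to stay desk-scale), grid stride 1 with configurable decimation for large
networks.  Per-macrostate seeds derive from one root seed via
`SeedSequence.spawn`, so every run is reproducible.

The sampled tables (q̄s, mean H-bond energy, mixing entropy) do not depend
on the numerical parameter values, only on the entropy *ranking* of
constraint classes — so they are computed once per network and reused
across parameter evaluations, which makes C_p fitting cheap and makes
noise-free self-consistency of parameter recovery exact.

Free energy per cell: G = U + u_sol(N_hb^max − N_hb) + v_nat N_nat −
T(S_conf + S_mix), with S_mix the log-binomial counting term.  C_p comes
from enthalpy fluctuations under Boltzmann weights (smooth on coarse
grids, unlike numerical differentiation); T_m is the interior grid
argmax, and a flat curve or boundary peak raises a diagnostic error.  The
reference parameterization is {u_sol = −2.71 kcal/mol, v_nat = −0.89
kcal/mol, δ_nat = 1.89}, with δ_dis = 2.125 held fixed (δ_dis is not
fitted).  R = 1.9872 × 10⁻³ kcal/mol/K.

**Native basin.** The 4-connected set of grid cells within ΔG_cut
(default 3RT — thermally accessible cells; configurable) of the local
minimum with the larger N_nat.  A unimodal landscape returns the whole
low-G region with a warning.

**Fitting.** Least squares over {u_sol, v_nat, δ_nat} with dispersed
multi-starts (the u_sol/v_nat valley is strongly correlated and can host
secondary branches).  The nuisance alignment of model to data is
configurable: amplitude + linear baseline (experimental DSC traces),
amplitude only, or none.  Parameter-recovery validation uses no alignment
because synthetic curves are generated by the model itself on its absolute
scale; fitting nuisance parameters the data cannot contain would only
dilute identifiability.

## QSFR metrics

Per topology, every rotatable bond receives f = h − l (h = A/H from its
flexible region; l = B/L from its stressed region; 0 when isostatically
locked — note l, hence |f|, is not bounded by 1 and no cap is applied).
FI averages f over topologies (equal weight within a macrostate) and over
native-basin macrostates (Boltzmann weight at T = T_m).  CC is assembled
the same way over backbone φ/ψ bonds only: +h for pairs sharing a flexible
region, −l for pairs sharing a stressed rigid region, 0 otherwise; bonds
co-rigid in an unstressed (isostatic) cluster contribute 0.  Residue-level
profiles average a residue's backbone bond values.

## Ensemble comparison

Frames are clustered by leader (radius) clustering on CA+CB RMSD after
optimal superposition, the radius bisected until the cluster count is
within ±10% of the target (default 20); representatives are each cluster's
RMSD medoid (the discrete "nearest to centroid") and carry the cluster
population as weight.  Weighted means/SDs feed the Z-score
(x̄_m − x̄_w)/√((σ_m² + σ_w²)/N_rep) with N_rep = 10 by default; the
sum-of-variances form and the one-tailed reading of the thresholds
(2.33 → p = 0.01, 3.33 → p = 0.0005) are recorded in the profile metadata.
When both SDs vanish, equal means give Z = 0 and unequal means a signed
infinity sentinel classified by sign.  H-bond occupancy is keyed on
donor/acceptor heavy atoms (hydrogens ignored, so proton flips do not
split a bond); bonds at ≤ 50% occupancy are excluded from reported
networks, and the displayed classes partition (0.5, 1] at 0.7 and 0.9.

The pipeline evaluates each representative's C_p on a wide default grid
(60–700 K) and, if the peak falls outside, retries once on a maximal grid
before failing: weakly bonded frames of small model peptides can melt far
below the physiological range.

## Synthetic data: what it emulates, what it does not

Toy frameworks provide networks with analytically known rigidity.  Peptide
ensembles are idealized backbones built from canonical internal coordinates
(α-helix φ/ψ = −57°/−47°; hairpin and coil variants), with one pseudo-Cβ
and the amide hydrogen per residue, so that every designed i→i+4 helix
H-bond passes the detection criteria exactly in unperturbed frames.
Frames differ by isotropic Gaussian coordinate noise and by designed-bond
toggling implemented as acceptor displacement beyond the distance cutoff —
the detection code remains the single source of truth for whether a bond
exists.  Bonds can be pinned to exact occupancies by a deterministic
schedule or suppressed entirely (a planted mutation).

None of this emulates force-field energetics, solvent, side-chain
chemistry or realistic conformational kinetics.  Passing tests therefore
demonstrate the *machinery* — detection, counting, sampling, statistics —
on geometrically faithful inputs, not predictive accuracy on real
proteins, which additionally depends on structure preparation and
parameterization quality.

## Validation studies and problem sizes

The studies in `qsfr.validation` run at sizes chosen for a desk machine:
500 random ≤8-body frameworks against the rank oracle; 30 networks × 100
random placement orders for the entropy bound; a single-torsion two-level
network with a large gap (so the finite-gap corrections to the two-state
closed form sit well inside the 1% band) for the C_p closed form; a
10-residue helix (≈60 atoms, 500-point C_p curve, 2%-of-peak noise) for
parameter recovery; and 14-residue, 30-frame ensembles with 10% H-bond
toggling for the planted-mutation comparison, where the suppressed bond
spans residues 10→14 and residues 1–6 serve as the distal control.  In
short helices rigidity is genuinely long-ranged, so the distal criterion
is assessed on the median |Z| — occasional distal excursions are the
model's real long-range coupling, not noise.

## Known limitations

* Rigid clusters are the closure of pairwise-rigid adjacent bodies; exotic
  generic frameworks could in principle contain mutually rigid bodies not
  linked through adjacent rigid pairs, which this decomposition (and its
  oracle) would split.
* The H-bond energy function and the γ map are monotone surrogates; only
  their ordering is load-bearing.
* Choices the formulation leaves open: the presence probability in the
  H-bond entropy sum is the uniform p_t = N_hb/N_hb^max, and the mean
  H-bond energy U excludes any torsion-independent packing energy beyond
  v_nat·N_nat.
* A single unfolding transition is assumed (no two-domain model), and no
  per-mutant re-parameterization of {u_sol, v_nat} is provided.
* Kabat renumbering is out of scope; a user-supplied residue-label map is
  accepted where mutant and wild-type numbering differ.
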