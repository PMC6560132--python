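# Methods

## Scope and model

`bindprof` quantifies receptor–ligand interactions along a molecular
dynamics trajectory and validates the resulting binding-residue predictions
against site-directed mutagenesis data. The pipeline has five stages:
per-frame geometric contact detection, persistency aggregation, binding
calls, confusion-matrix scoring, and representative-snapshot selection, with
Ballesteros–Weinstein (BW) numbering as a reporting aid. All coordinates are
Å, times are ns, residue numbering is 1-based PDB convention.

No periodic-boundary handling is performed: the intended inputs are
membrane-free simulation setups (e.g. hybrid MM/CG systems confined by wall
potentials), so molecules must be whole in every frame.

## Contact criteria

**Hydrogen bonds.** Donors are N/O atoms with at least one covalently bonded
hydrogen (one donor–hydrogen pair per hydrogen); acceptors are all N/O
atoms. Sulfur is excluded by default — glycoside ligands and the cavity
residues of interest carry only N/O polar atoms — and the typing is applied
identically to receptor, ligand and water. A bond exists when
d(D,A) ≤ `d_max` (default 3.5 Å) and the D–H–A angle, measured at the
hydrogen, deviates from linearity by at most `theta_dev_max` (default 30°,
i.e. angle ≥ 150°). The "angle made by donor, hydrogen and acceptor" is
deliberately fixed to the at-hydrogen convention used by the common
visualization tools. Both donor directions (receptor→ligand and
ligand→receptor) count, and events are keyed by the receptor residue.

**Water bridges.** Same criteria; a bridge for residue R exists in a frame
when one water molecule simultaneously H-bonds (donor or acceptor role) an
atom of R and a ligand atom. The bridging water's residue number is
recorded; multiple waters bridging the same residue collapse to one
presence per frame.

**Hydrophobic contacts.** Minimum distance between residue carbons and
ligand carbons ≤ `d_max` (default 5.5 Å — the sum of two carbon van der
Waals radii plus the diameter of an interposed water). A `carbons_only=False`
switch extends the groups to all heavy atoms, since minimum-distance tools
in MD packages are group-generic and the original group definition is not
recorded anywhere authoritative.

All boundary comparisons are inclusive (≤ cutoff, ≥ 150°): one consistent
rule rather than undocumented tool internals. Detection uses KD-trees but is
exactly equivalent to all-pairs enumeration; the tests assert this
equivalence on randomised frames.

**Bond inference.** Connectivity is inferred from frame-0 geometry: two
atoms bond iff their distance ≤ 1.3 × the sum of covalent radii; each
hydrogen is then pruned to exactly its nearest heavy atom, and a hydrogen
with no heavy atom within 1.5 Å is rejected. Inference is frame-0-only and
deterministic. No protonation or topology repair is attempted — structures
must carry explicit hydrogens.

## Persistency and classification

Persistency of (residue, kind) is the number of analysed frames containing
at least one such event divided by the number of analysed frames. The
analysed window drops every frame with time < `exclude_time` (default
100 ns) from numerator *and* denominator; e.g. 160 frames spanning 0.8 μs
leave exactly 140. Frame times absent from PDB input are reconstructed as
`index × dt`, with `dt` defaulting to `0.8 μs / n_frames` (the frame-saving
stride of the original trajectories is not recorded, so `dt` is explicit
configuration, not an asserted value).

A residue is called *binding* when its H-bond persistency > 10% **or** its
hydrophobic persistency > 80%. Both bounds are strict ("higher than"), and
the asymmetry is intentional: hydrogen-bond networks fluctuate far more
frame-to-frame than hydrophobic packing. The H-bond statistic facing the
10% bound is, by default, the frame-level union of direct and
water-mediated events (a union of frame sets, never a sum of fractions —
whether the original classification included the water channel is not
documented, so both channels are always reported and
`hbond_channel="hbond_direct"` selects the alternative). For static docked
poses there is no time axis; the persistency criterion is replaced by
presence/absence of any interaction in the single pose, which is equivalent
to trajectory mode on a one-frame window with the exclusive bound replaced
by presence.

## Experimental labels and scoring

Mutagenesis annotations are declarative CSV input: per residue, whether
mutation shifts EC50 (a curated boolean — published effects range from
0.9× to 55×, and no fold-change threshold is canonical, so none is imposed;
`flag_ec50_affected` offers an explicitly non-canonical ≥2-fold helper) and
whether the residue lies in the upper extracellular or lower intracellular
part of the receptor (an input column, since deciding it requires the 3D
model). *Experimental binding* = EC50-affected AND upper region; everything
else annotated is *experimental non-binding*.

Scoring compares calls only on experimentally annotated residues.
PREC = TP/(TP+FP), REC = TP/(TP+FN); true negatives are tallied but never
scored, because mutagenesis panels target suspected binding residues and
the TN pool is tiny (one of seven here). TP = 0 reports both scores as 0.0,
with a degenerate flag when a denominator is also zero. Display values are
truncated (not rounded) to two decimals — 4/6 renders 0.66 — with full
precision retained in JSON.

The packaged annotation fixture holds the seven-residue hTAS2R16 panel
(E86, N89, F93, Q177, H181, F240, I243; Q177 is the sole experimental
non-binding residue). The published account leaves the false negative of
the high-recall columns ambiguous ("F240 and/or I243"); the call fixtures
use F240 as the predicted residue and I243 as the FN — swapping them changes
no score. A second, clearly marked *extended* fixture adds W85, L59, F236,
E262 and V265, whose membership in the scored panel cannot be resolved from
the main text; response-amplitude-only effects are encoded as
`ec50_affected=false`.

## Representative snapshot

The average structure is the per-atom mean over frames after least-squares
(Kabsch) superposition of each frame onto frame 0 using the non-water atoms.
The representative frame minimises the RMSD of a subset — TM helices plus
ligand, heavy atoms by default, hydrogens being force-field noise — to that
average, after superposing the subset itself; ties break to the lowest frame
index. Fit region = computation region for the per-frame RMSD; the original
tooling does not record its fit groups, so both the subset and an `all`-atom
switch are configuration.

## BW numbering

`position = 50 + (res_seq − anchor_res_seq)` within an explicit per-helix
anchor range; anchors come from an alignment or the literature (no MSA is
computed). The packaged hTAS2R16 anchors place residue 103 at 3.50, which
reproduces every published superscript for this receptor (E86 = 3.33,
N89 = 3.36, …, E262 = 7.39, Y266 = 7.43). Loop residues get no number.

## Synthetic data

The generator builds a cartoon binding cavity: ≥ 2 facing pseudo-helices at
13 Å radius with serine-like hydroxyl residues in the upper half and
leucine-like carbon side chains in the lower half, a glycoside-like ligand
(pyranose C/O ring, four hydroxyls, exocyclic C6–O6, three-carbon aglycon
tail) at the centre, and a distant water shell. Contact schedules plant, per
(residue, kind), a target persistency; "on" frames are spaced evenly over
the analysed window with count `round(target × n_analysed)`, so the realised
fraction is exact and threshold-boundary tests are meaningful. On-frames
pose the interacting atoms well inside the criteria (D–A 2.9 Å collinear;
bridge chains ligand–2.8 Å–water–2.9 Å–hydroxyl, posed radially outward
from the ligand centroid; C–C 4.5 Å), off-frames rest ≥ 1 Å outside every
cutoff, and a ±0.02 Å seeded jitter decorrelates coordinates between seeds
without eroding those margins.

The packaged study (`bindprof.study`) instantiates seven complexes — three
ligands × two binding modes at 160 frames × 5 ns, plus a contact-free docked
pose — with schedules chosen so the classifier reproduces the published
per-complex call sets; the water-mediated channel is exercised through H181
in the arbutin complexes. What passing these tests shows is that the
*analysis* is correct: the generator has no force field, no sterics and no
conformational noise beyond placement, so it says nothing about simulation
quality, force-field realism, or how persistencies behave under genuine
thermal fluctuation (no block averaging or autocorrelation error bars are
provided, matching the original analysis).

## Problem sizes and numerics

Default desk-scale sizes: 62-atom study system, 160-frame trajectories,
≤ 1000-atom oracle-equivalence fixtures; these keep the full test suite and
the acceptance script in the seconds range. Fractions are exact rational
counts over analysed frames; superposition uses
`scipy.spatial.transform.Rotation.align_vectors`; angle computations clip
cosines to [−1, 1]. Degenerate inputs fail loudly: empty analysis window,
zero-hydrogen structures, carbon-free ligands, multi-frame input in static
mode, conflicting schedule entries, overlapping helix ranges.

## Known limitations

* Donor/acceptor typing is geometric, not chemical — no charge states, no
  sulfur donors, no aromatic (π-stacking/T-stacking) or cation–π criteria;
  the aromatic-cluster effects discussed qualitatively for this receptor
  family are out of scope.
* Binary trajectory formats (XTC/DCD) are not read; convert to multi-model
  PDB upstream (the `Trajectory` container is format-agnostic if a reader
  is added).
* `ec50_affected` curation is upstream of the package; no dose–response
  fitting is performed.
* The classifier has exactly two categories; "shaping"/second-shell roles
  are narrative, not a formal class.
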