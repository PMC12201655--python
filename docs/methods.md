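# Model and methods

`ribocell` simulates the early evolution of RNA-based protocells on an
`N x N` toroidal grid of rooms, at single-nucleotide resolution.  The model
asks a narrow question: if an RNA sequence motif confers a function on the
protocell carrying it, can that motif spread by Darwinian dynamics — in
particular, can a ribozyme that feeds phospholipid synthesis drive the
membrane from pure fatty acids toward phospholipids, and can the resulting
permeability drop then select for species that exploit more permeable
substrates (NPR) or enhance transport (TR)?

## State

* **Rooms** hold integer counts of small molecules: nucleotide-precursor's
  precursors (Npp), nucleotide precursors (Np), nucleotides (Nt, per base),
  glycerophosphate precursors (Gp), glycerophosphates (G), fatty acids (FA)
  and phospholipids (PL).
* **RNA strands** are explicit base strings over {A, C, G, U}, stored 5'→3'.
  A strand may carry a duplex: a contiguous block of substrate residues
  aligned on it, with per-junction ligation state.
* **Protocells** occupy a whole room: a membrane (FA and PL counts; size
  `b` counted in tails, one per FA, two per PL) encloses the room's pools
  and strands as its interior.

The system is closed: nucleotide equivalents (Npp + Np + Nt + RNA
residues), fatty-acid equivalents (FA + 2·PL) and glycerophosphate
equivalents (Gp + G + PL) are conserved by every event.  Inoculation events
add material explicitly and log it.

## Events and their probabilities

Each Monte Carlo step applies five phases in a fixed order (free-molecule
movement and membrane crossing; small-molecule reactions; RNA events;
membrane events; protocell events), with randomized entity order inside a
phase and phase-start staging so that products act from their next
opportunity on.  All constants live in a single flat `ParameterSet`
(see `ribocell/data/table1.yaml` for the shipped defaults).  The closed
forms:

* movement: `P_MV` for small molecules, `P_MV / sqrt(m)` for an RNA complex
  of `m` residues (Zimm scaling);
* membrane formation in a room with `a ≥ L_AM` amphiphile tails:
  `1 − (1 − P_MF)^(a − L_AM + 1)`;
* amphiphile desorption: `P_FLM/(y·z)` (FA) and `P_PLM/(y·z)` (PL) with the
  osmotic term `y = 1 + i/(b/2)^(3/2)` (`i` = interior RNA residues, the
  impermeable ions) and the anti-desorption term `z = 1 + F_PL·RPM`,
  `RPM = 2·pl/(2·pl + fa)`;
* permeation into a protocell: base rate × `s/(u·v)` with volume factor
  `s = b/L_AM`, Donnan term `u = 1 + F_DE·i/(b/2)^(3/2)` and phospholipid
  throttle `v = 1 + F_PP·RPM` (weak variant `F_PPW` for Npp and Gp; no
  Donnan term for the uncharged Gp).  Outward crossing omits `s` and `u`.
  TR relief replaces the Np throttle by `1 + F_PP·RPM/(1 + t·F_TR)` in both
  directions, `t` = free TR strands inside;
* division: `max(0, P_CD·(1 − 2·L_AM/b))`, with independent fair-coin
  assortment of every amphiphile, molecule and strand;
* backbone bond breaking `P_BB` per single-stranded site (`(P_BB)^{3/2}`
  severing both strands at paired sites), chain-end residue decay `P_NDE`;
  both ×`F_DO` outside protocells, as is nucleotide decay `P_ND`.

Catalysis is presence-gated: one or more *free single* strands carrying the
relevant domain (GR/NR/NPR) switches its compartment's reaction to the
catalyzed rate; duplexed templates are inert, and copy number does not
stack.  Domain recognition is exact contiguous substring match on the
stored sequence; the complementary strand does not confer function.

## Template-directed replication

A template attracts one substrate per step with `P_AT`: the complementary
nucleotide or a fully complementary bare oligomer from the same
compartment, in proportion to their counts, at the next unpaired position
adjacent to the aligned block (a uniformly chosen position on a bare
template; a uniformly chosen end when both are extendable).  With `P_FP`
the incorporated monomer is instead a uniformly chosen non-complementary
base in stock.  Adjacent aligned residues ligate with `P_TL` per junction
per step.  Separation distinguishes loose substrates from the growing
copy: an *unligated* lone monomer at a block edge falls off with `P_SP`,
while the *full complementary chain* — the block spanning and fully
ligating the template — leaves with `P_SP^sqrt(L)`.  Ligated partial runs
are anchored by their base pairs and stay until the copy completes, so
synthesis ratchets toward faithful full-length products; nascent strands
are recorded 5'→3' as the reverse complement of the template.  Chains
shorter than `L_TMIN` never act as templates.

Three replication choices deserve justification, because the source
description underdetermines them and the observable behavior of the system
is extremely sensitive to the criticality of short-RNA copying:

1. **`P_TL = 0.2`.**  The reference constant table garbles this entry
   ("0..02").  Read as 0.02, template copying is roughly fifty-fold slower
   than chain-end decay under every mechanistic variant we analyzed
   (single-template completion-rate calculations and micro-world runs), so
   no lineage — functional or not — can ever replicate, and every reported
   evolutionary outcome becomes impossible.  We therefore read the value as
   0.2, which satisfies the stated ordering `P_TL >> P_RL` and makes 7-mer
   replication comfortably viable inside protocells.
2. **`L_TMIN = 7` (minimum template length).**  If arbitrarily short chains
   template, a 2-mer is the fittest replicator in the model: its nucleation
   *is* a complete copy, and self-replicating dinucleotide junk absorbs the
   entire nucleotide inventory within ~4×10⁴ steps, starving every
   ribozyme.  Physically a one-or-two-pair hybrid has no helical stability
   — the same physics the `P_SP^sqrt(n)` law encodes — so chains shorter
   than `L_TMIN` do not hold substrates.  With the threshold at the
   characteristic-domain length, replicators must be at least domain-sized,
   random junk arises only through rare compounded random ligations, and
   the Npp pool visibly persists, as the modeled system requires.
3. **Completion-ratchet separation.**  Releasing every partial product
   (all aligned segments at once, or per-segment) floods the compartment
   with short fragments that recombine into chimeras and dilute domains
   away within ~10⁵ steps.  Anchoring ligated runs until full length keeps
   copying faithful while still letting loose substrates exchange; the two
   printed operating points (a lone pair separating with `P_SP`, a full
   duplex with `P_SP^sqrt(n)`) are unchanged.

## Scenarios and scaling

Named scenarios encode the reference experiment designs: `fig2a` (an empty fatty-acid
protocell inoculated at step 10³; ten empty protocells each given one GR
molecule, ten given one control, at step 10⁴), `fig2b`/`fig2c` (sequential
NR/GR inoculations), `fig2d` (no RNA inoculation, raised `P_RL`, GR domain
two bases from NR's), the `fig3_*` staircase parameter scans, and
`fig6a/b` (NPR/TR inoculated into NR-GR protocells with the permeability
influence off, or switched to `F_PP = 30`, `F_PPW = 3` beforehand).  The
reference trajectories mark the staircase adjustment points without
printing all of them; the scans use an evenly spaced grid ending at the two
documented late switches.

Each scenario has a *scaled* desk variant: a 12×12 grid with the material
totals shrunk by the area ratio so that every per-room density matches the
full 30×30 system (Npp 12 800, FA 8 000, Gp 8 000), and horizons shortened
to where the outcome is already decided (the GR-vs-control contrast is
fully resolved by ~4×10⁴ steps after inoculation at this size).  Event
probabilities, thresholds and inoculation designs are never altered by
scaling.  At full scale (30×30, 3×10⁵ steps) the simulator reproduces the
reference behavior: protocells fill the grid within 10⁴ steps, GR-bearing
protocells take over the population (~165 of ~167 cells) while the control
species goes extinct by ~7×10⁴ steps, the membrane phospholipid pool rises
roughly 50-fold to a partial takeover, and about 30% of the Npp inventory
remains free.

What the scaled runs do not show: spatial pattern formation on large
grids, the multi-million-step staircase scans, and very-low-probability
events (natural ribozyme emergence at default `P_RL`) that need the full
system's opportunity count.

## Numerical choices

* Counts are drawn with aggregated binomial/multinomial sampling per room —
  exactly equivalent to independent per-molecule Bernoulli trials.  The
  hottest fixed-probability draws (uniform 4-way splits, fair-coin
  assortment, movement) use precomputed Vose alias tables per (n, p),
  built stably in log space; all other draws use the runtime's binomial
  sampler.  No Gaussian or Poisson approximations are used anywhere, so
  conservation is exact by construction.
* A single kernel RNG stream drives all per-step events, seeded once per
  run from the master seed; world initialization and inoculation target
  selection use a separate generator spawned from the same seed.  Runs are
  bit-reproducible given `(parameters, schedule, steps, seed)`.
* Strand storage is a structure-of-arrays slab with a free-slot stack and
  a 48-residue width; random ligations that would exceed the width are
  skipped (template products can never exceed it).  Displaced molecules
  during protocell movement/division are pushed to the target room's
  unoccupied neighbors, falling back to the vacated room (movement) or the
  offspring interior (division) when fully walled in.  Amphiphiles leaving
  a membrane go inside or outside with probability 1/2 each; the outside
  share lands in a random unoccupied neighbor room.
* Outward permeation into a room occupied by another protocell fails (the
  molecule stays inside); glycerophosphates react with membranes only from
  the interior side.

## Replication economy and late inoculations

Inside a mature protocell the RNA population sits at a carrying capacity
set by the nucleotide influx and the decay constants — typically tens of
strands with the free nucleotide pool drawn down to a handful.  Every
strand in a compartment draws on the same monomer pool, so *within* a cell
all lineages replicate at the same rate and their relative shares follow
neutral drift; selection acts only *between* cells.  Two consequences are
verified by the simulator and matter for interpreting the scaled
experiments:

* A functional species inoculated into *empty* protocells (GR in the
  flagship scenario) establishes readily — the founder is a large share of
  a near-empty interior — and then spreads at cell level.  This outcome is
  robust (6/6 seeds at desk scale; reproduced at full scale).
* A species inoculated as a single molecule into *saturated* protocells
  joins as a few-percent minority whose compartment-wide benefit (e.g.
  NPR's nucleotide-precursor synthesis) is shared with every resident
  competitor.  Its lineage usually drifts out before cell-level selection
  can amplify it, so the NPR/TR follow-up experiments do not reproduce
  their reference outcome under this replication economy; the
  permeability-cost *necessity* direction (no spread without the cost)
  does reproduce.  The shipped scenarios keep the original designs so the
  behavior can be studied directly.

## Limitations

* The membrane has no leaflet structure, no flip-flop kinetics and no
  explicit geometry beyond the `b/2` area and `(b/2)^(3/2)` volume scale
  relations; a protocell occupies exactly one room.
* No secondary structure, folding thermodynamics, wobble pairing,
  recombination or self-priming; energy and activation chemistry are
  implicit (all substrates are assumed activated).
* Functional activity requires the exact domain on the stored strand; the
  complement is silent.  This makes function loss/regain sharp rather than
  graded.
* The replication micro-mechanism (ratchet separation, template length
  threshold, the `P_TL` reading) is this package's own resolution of an
  underdetermined description, chosen as the minimal rules under which the
  modeled system's reported ecology is self-consistent; alternatives are
  discussed above and their failure modes documented.
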