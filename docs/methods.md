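# Methods

This note documents the statistical model behind `methylogo`, the
estimators and their numerical choices, what the synthetic-data
generator does and does not emulate, and the design decisions taken
where more than one reasonable convention exists.

## Coordinates, contexts and input conventions

All coordinates are 0-based, half-open `[start, end)` internally. BED
input is taken as 0-based half-open; TSS tables may be declared 1-based
at the reader boundary. A cytosine is addressed by
`(chrom, pos, strand)` where `pos` is the position of the cytosine base
on its own strand (so a `-` strand cytosine sits where the genome shows
`G`).

The trinucleotide context of a cytosine (CG, CHG, CHH; H = A/C/T) is
read from the one or two bases immediately downstream *on the cytosine's
strand*. Context is a genomic property: the context of a site's last
cytosine can depend on bases beyond the motif, which is why site
extraction requires a flank of at least 2 bp and why sites too close to
a chromosome edge are dropped (with a warning) rather than truncated.
Cytosines whose context window runs off the chromosome or contains N
are labelled UNDEFINED and excluded from every numerator *and*
denominator — an UNDEFINED cytosine is treated as unclassifiable, not
as a seventh class.

WGBS methylation-call tables differ by pipeline; parsing is
dialect-driven (generic percent TSV, ENCODE bedMethyl, Bismark
per-cytosine report) rather than hard-coded. Replicate merging applies
the read-depth filter (depth > 4, i.e. keep depth ≥ 5) *per replicate*
and then averages the levels of the replicates in which the site
passed, unweighted. A site passing in only one replicate is kept with
that replicate's level; `require_all=True` switches to the stricter
intersection rule. The depth threshold and the averaging rule are
deliberately simple — methylation levels are beta-valued fractions and
the mean of passing replicates is used as a Bernoulli parameter
downstream.

## Background models

Backgrounds are estimated over a region set — the whole genome, or
promoter windows built as TSS −1000/+200 bp strand-relative (the `-`
strand window is the exact genomic mirror, `[t−199, t+1001)`) — always
counting **both strands**, which is what a strand-agnostic background
should do and which forces q(A)=q(T), q(C)=q(G) exactly.

* **Zero-order**: base frequencies over the covered sequence plus its
  complement; N skipped; pseudocount 1.0 per cell by default.
* **First-order**: joint dimer probabilities `q(a,b)` from overlapping
  dimers within each contiguous covered block; each dimer also
  contributes its reverse complement; no dimer spans a region boundary;
  pseudocount 1.0 per cell. The chain emits its first base from the
  left marginal of the joint.
* **Context methylation** `m_bg(ctx)`: the mean merged methylation
  level of every table cytosine of that context inside the regions,
  strands pooled. A context with zero contributing cytosines is a hard
  error (the track cannot be computed without a background level);
  values are clamped into `[1e−4, 1−1e−4]` so saturated methylomes
  yield finite heights.

**Exactness of the dimer decomposition.** The dimer track displays
`D(M‖B₁) − D(M‖B₀)` split into one term per adjacent pair. The split is
algebraically exact precisely when B₀ is the left marginal of B₁'s
joint and B₁ emits its first base from that marginal; the oracle tests
verify this to 1e−9 against exhaustive enumeration. For *estimated*
backgrounds one more step is taken: linear (non-circular) dimer
counting leaves the left marginal strand-symmetric only up to per-block
boundary terms, so the bundle's zero-order model is the marginal
averaged with its own complement. This restores exact strand symmetry —
required for reverse-complement invariance of the tracks — at the cost
of an O(1/coverage) deviation from the exact decomposition, about 1e−5
bits on a 1 Mb background and irrelevant at display resolution.

Pseudocount defaults (1.0 for backgrounds, 0.5 per cell for motif base
and dimer counts) avoid log(0) while perturbing large-sample estimates
negligibly; both are parameters, and the pair-marginal consistency
identity `Σ_b p_{i,i+1}(a,b) = p_i(a)` holds exactly at pseudocount 0.

## Motif model and tracks

From the aligned site matrix (minus-strand sites reverse-complemented
into motif orientation, strand labels swapped accordingly) the motif
model records per position: base probabilities `p_i`, adjacent-pair
joints `p_{i,i+1}`, and — strand-resolved — the context probabilities
`P(ctx,s|i)` and mean methylation `m_{i,ctx,s}` of the six
(context, strand) classes. Context/methylation statistics use raw
fractions without pseudocount: the multiplicative `P(ctx,s|i)` term in
the track formula already damps rare classes, which is also why the
methylation track is robust to small-sample noise in `m`. A class with
cytosines but no surviving methylation observation (all sites failed
the depth filter there) is skipped with a warning rather than invented.

Track formulas are in the README. Heights are bits (base-2 logs)
throughout. The expected-methylation dashed line at position `i`,
strand `s` is `Σ_ctx P(ctx,s|i)·m_bg(ctx) / Σ_ctx P(ctx,s|i)`, defined
only where the denominator is positive; glyph shading uses the same
weighting applied to the observed `m_{i,ctx,s}`.

The wide-window profile generalizes the methylation track to offsets
`[-W, L+W)` with strands pooled after motif orientation: per offset and
context it reports the context probability, the mean methylation, and
`P_ctx(d)·KL2(m(d,ctx) ‖ m_bg(ctx))`. The weighted form is the default
because it is the same quantity the logo's methylation track stacks per
column; `weighted=False` reports plain KL2 where the context occurs.
The default window is 500 bp, configurable; the examples and tests use
small windows to keep synthetic genomes small.

## Rendering

Figures are built as a backend-independent primitive list and written
as hand-assembled SVG 1.1 (primary) or through matplotlib (PDF/PNG).
Three choices make the SVG machine-checkable, and are also why repeated
renders are byte-identical:

* each letter is a unit-box outline under `translate(x y) scale(w h)`,
  so its rendered height is the y scale factor and bits = points /
  `points_per_bit`;
* methylation shading is a clipped overlay rectangle in glyph-local
  units whose height *is* the methylation fraction (not a gradient);
* every data-bearing element carries `class` and `data-*` attributes.

Letters stack with the most probable base on top. The six methylation
components use one hue per context with a lighter tint for the reverse
strand (six distinct colors; a tint was preferred over hatching to keep
the SVG and matplotlib backends pixel-consistent). Base colors follow
the common logo palette (A green, C blue, G yellow, T red). The key box
lists `m_bg(CG/CHG/CHH)` and the four base frequencies; the figure
label (`WG`/`PR`) names the background.

## The simulator: scope and limits

The generator emulates the study conditions the pipeline is designed
for: a zero- or first-order Markov genome (with a convenience
CG-depleted transition, P(G|C) suppressed 4–5×), per-context true
methylation levels (defaults CG 0.8, CHG 0.05, CHH 0.02 — a
mammalian-like profile), planted equal-length sites drawn from a
consensus or PWM on random strands with an exclusion margin so context
windows never collide, and two replicate call files with depth fixed or
Poisson (default mean 30) and observed level Binomial(depth, true)/depth.
All draws derive from one mandatory seed; outputs are byte-reproducible.

What it does **not** emulate — and what passing tests therefore do not
show about real data: read-level bisulfite chemistry (conversion
failure, mapping bias, strand coverage imbalance), copy-number and
mappability structure, correlated methylation between neighbouring
cytosines, cell-to-cell heterogeneity (levels are means over many
cells), and imperfectly aligned or variable-length binding sites (the
pipeline requires pre-aligned equal-length intervals by contract).

## Problem sizes

The test suite and acceptance script choose sizes where the quantities
they check are already stable: 100 random (motif, background) instances
with L ≤ 5 for the enumeration oracle (4^L terms each), 1 Mb and depth
30 for background parameter recovery (all estimates land within well
under ±0.02 of truth), and 80–200 kb genomes with 100–150 planted sites
for the localization studies. Larger inputs change nothing qualitative;
the estimators are linear-time in covered bases.

## Known limitations

* Backgrounds above first order (trimer tracks) are out of scope.
* 5-hydroxymethylcytosine is not distinguished (standard bisulfite data
  conflates it with 5mC).
* Overlapping background regions are counted as given (no interval
  merging); supplying a merged region set is the caller's choice.
* The dimer track is bars only (no lettered dimers), and the sequence
  track is classical relative entropy (no enrichment/depletion
  rescaling).
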