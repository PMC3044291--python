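# apfbss — binding-site superposition and comparison with atomic property fields

`apfbss` superposes and compares protein–ligand binding pockets using
continuous pharmacophoric fields rather than discrete matched points.  It is
aimed at structural bioinformaticians who want to detect distant or
convergent similarity between binding sites — cases where residue identity
and fold have diverged but the chemistry lining the pocket has not — and to
cluster collections of pockets by that similarity.

## Method

A binding site is the set of receptor heavy atoms within 6 Å of any atom of
the bound ligand.  Each atom *j* carries a 7-component property vector
P(j) = (donor, acceptor, lipophilicity, size, electronegativity, charge,
sp2), assigned from a residue/atom-name typing table.  The template site's
properties are projected into space as Gaussian **atomic property fields**,

    φ_k(x) = Σ_j P_k(j) · exp(−|x − r_j|² / w²),       k = 1…7,

sampled on a 0.5 Å grid.  A probe site placed in these fields with rigid
pose *g* (3 translations + 3 rotations) has pseudo-energy

    E_APF(g) = − Σ_k w_k Σ_i P_k(i) · φ_k(g·r_i),

so stronger property overlap is more negative.  The pose is globally
optimized by pseudo-Brownian Monte-Carlo: random rigid move → bounded local
gradient minimization → Metropolis accept/reject (kT_eff = 10), terminating
after 10,000 energy evaluations; the best pose is polished and rescored
against the exact Gaussian double sum.

For comparison and clustering, optimal energies are normalized to

    S_APF = tanh((E₀ − E_APF)/Δ₀),   E₀ = −250, Δ₀ = 100,
    D_APF(A,B) = S_APF(A,A) + S_APF(B,B) − 2·S_APF(A,B),

a distance that is zero for identical pockets and grows with dissimilarity.
All-vs-all D_APF matrices are clustered with UPGMA (average linkage,
ultrametric tree).

## Worked example

Everything is testable without downloads via the synthetic-site generator:

```sh
apfbss fixtures --out fx --n-sites 4 --seed 3
apfbss superpose fx/fam0_m0.pdb fx/fam0_m1.pdb --seed 1 --evals 2000 --out-prefix sup
```

prints (abridged):

```json
{
  "template": "fam0_m0",
  "probe": "fam0_m1",
  "e_apf": -11.542608513512558,
  "evaluations_used": 2000,
  "accepted_moves": 48,
  "seed": 1
}
```

`e_apf` is the optimal pseudo-energy of the probe pocket in the template's
fields (more negative = more similar property distributions; here the two
sites are jittered copies from the same family, so the overlap is clearly
negative).  The transformed probe is written to `sup.pdb`, the pose as a
4×4 homogeneous matrix in `sup.json`, and the best-energy trajectory to
`sup.trace.tsv`.  Then:

```sh
apfbss matrix fx --out d.tsv --seed 2
apfbss cluster d.tsv --out t.nwk --order o.txt
cat t.nwk
```

```
(('fam0_m0':0.00241033251248445,'fam0_m1':0.00241033251248445):0.02621576960866196,('fam1_m0':0.005344588102502,'fam1_m1':0.005344588102502):0.023281514018644412);
```

— the UPGMA tree over the D_APF matrix: members of each family (jittered
rigid copies of one parent pocket) merge first at small distances, and the
two unrelated families join only at the root.

The same works on real PDB complexes (`apfbss superpose A.pdb B.pdb
--ligand-a TPP ...`); the bound ligands never enter the optimization, so
the RMSD between them after superposition (`ligand_rmsd` in the report) is
an independent quality check of the site alignment.

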