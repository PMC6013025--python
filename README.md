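# duofilm

Individual-based simulation of antibiotic response in two-lineage
biofilms.

## The problem

How a bacterial community responds to an antibiotic depends not only on
who is resistant, but on how the resistant (R) and susceptible (S)
lineages interact metabolically and where they sit relative to each
other. If R and S compete, suppressing S frees up resources and space
and R blooms (*competitive release*). If they feed each other,
suppressing S starves R too (*mutualistic suppression*), and a
detoxifying R can shelter nearby S cells (*cross-protection*), with
spatial mixing deciding who is "nearby". `duofilm` simulates these
scenarios mechanistically for researchers studying antibiotic ecology in
structured microbial communities.

## The model

Cells are circular agents of unit depth growing on a substratum. Each
cell senses solute concentrations in its grid voxel and grows by Monod
kinetics; reaching the division radius it splits into two daughters,
which shove neighbours aside. Solutes (nutrients, metabolic by-products,
anti-competitor toxins, the antibiotic) diffuse from a well-mixed bulk
above the biofilm and are consumed/produced by the cells; because
diffusion is fast relative to growth, every field is relaxed to its
pseudo steady state each time step:

    D lap(C) + r(C, X) = 0

with Dirichlet bulk values above the biofilm front plus a boundary
layer, a no-flux substratum and laterally periodic boundaries.

Four media set the metabolic relationship (rates per unit biomass):

| medium | R growth | S growth |
|---|---|---|
| exploitation competition | (u−c)·N/(N+K) | u·N/(N+K)·Ki/(A+Ki) |
| interference competition | as above ·Ki/(T_S+Ki) , secretes T_R | as above ·Ki/(T_R+Ki), secretes T_S |
| non cross-feeding | (u−c)·N_R/(N_R+K) | u·N_S/(N_S+K)·Ki/(A+Ki) |
| cross-feeding | adds (u−c)·E_S/(E_S+K), secretes E_R | adds u·E_R/(E_R+K)·Ki/(A+Ki), secretes E_S |

Here u is the maximal growth rate (1/h), c the cost of resistance, A the
bacteriostatic antibiotic (inhibits S only, never kills), and T/E
secreted toxins/by-products. Substrate consumption is 1/Y per unit of
new biomass; resistant cells optionally remove antibiotic in proportion
to their growth (coefficient alpha, g antibiotic per g biomass — no
enzyme is released).

The *segregation index* of the R lineage summarises spatial structure:
`s_R = (p_local − p_global)/(1 − p_global)`, where `p_local` averages
the same-type fraction within a 10 um neighbourhood over R cells;
s ≈ 0 means randomly mixed, s ≈ 1 fully segregated.

## Worked example

```python
from duofilm import SimulationConfig, run_simulation
from duofilm.experiments import scaled_config

cfg = scaled_config("reduced", medium="crossfeeding", antibiotic_bulk=0.2,
                    seed=1)
res = run_simulation(cfg)
print(res.metrics.iloc[-1][["count_R", "count_S", "s_R",
                            "biofilm_height_um"]])
```

prints (cross-feeding coculture, high antibiotic, 24 h on the reduced
130 um domain):

```
count_R              2149.000000
count_S              1922.000000
s_R                     0.112105
biofilm_height_um      81.569231
```

i.e. about 2149 resistant and 1922 susceptible cells — the susceptible
lineage keeps growing despite the high antibiotic because its
cross-feeding partner sustains it — with the community still well mixed
(s_R ≈ 0.11) and an 82 um tall biofilm. The same run without antibiotic
gives R = 2238: antibiotic *reduces* the resistant lineage here
(mutualistic suppression), the opposite of the competitive-release
outcome in the competition media.

The command line mirrors the library:

```
duofilm suite fig1 --scale reduced --seed 1 --outdir out/
duofilm run --config my_config.yaml --outdir out/run1
```

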