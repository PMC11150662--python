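# fibronet

An agent-based spring-network model of self-healing and progressive
pulmonary fibrosis, for computational biologists and lung-mechanics
researchers studying how mechanotransduction shapes tissue remodeling.

Fibroblasts and myofibroblasts read two mechanical signals from the
extracellular matrix — substrate **stiffness** and **stretch** — and respond
by depositing or digesting collagen. `fibronet` models a patch of lung
parenchyma as a prestressed 2D network of Hookean springs (stiffness
`K = E·A/L0`, varying only through the cross-sectional area `A`) populated
by mobile agents whose signed activation integrates the two signals through
saturating Hill functions:

    a = w1·(ε/εs)^γ/((ε/εs)^γ+1) + w2·(A/At)^β/((A/At)^β+1) − c

with the constant `c` chosen so that `a = 0` at the homeostatic state
`(ε, A) = (εs, A0)`. Positive activation thickens the springs an agent
crosses (`ΔA = P·a`) and promotes division; negative activation digests
them and promotes death. Springs digested to `A ≤ 0` rupture irreversibly.
The stretch pathway is negative feedback (self-healing); the stiffness
pathway is positive feedback (fibrosis). Their competition creates a
**fibrotic threshold**: injuries below it heal, injuries above it trigger
runaway stiffening — and the threshold exists only when the stiffness
weight exceeds the critical value `w2 > w1/2`. On the network the threshold
blurs into a bifurcation band in which identical injuries can heal or turn
fibrotic depending on the random spatial structure of the damage, producing
emergent honeycombing, dense fibrotic patches and tissue contraction.

## Worked example

Inflict a single stiffening insult (8× the homeostatic area) on the lumped
single-element model with stiffness weight `w2 = 2`:

```
$ fibronet element --w2 2 --injury-multiplier 8 --out demo
INFO fibronet: element run: {'outcome': 'fibrotic', 'fibrotic_threshold':
6.03084135055542, 'critical_weight': 0.5005340576171875}
```

The run reports three numbers. The **outcome** is `fibrotic`: an 8× injury
exceeds this element's **fibrotic threshold** of ≈ 6.03 — the smallest area
multiplier from which the stiffness signal overpowers the stretch signal —
so the positive feedback wins. The **critical weight** ≈ 0.5005 is the
infimum stiffness weight (with `w1 = 1`) at which any fibrotic response is
possible at all; at one decimal it is the 0.5 stability boundary of the
model. The trajectory CSV shows the runaway in state space:

```
$ head -3 demo/element_trajectory.csv ; tail -1 demo/element_trajectory.csv
iteration,A,eps,a,D,outcome
0,8.0,0.125,0.0,0.3,fibrotic
1,8.008590853590853,0.124865911904043,0.14318089318089328,0.30115334700044044,fibrotic
2000,1662.2002198857733,0.0006016122414354633,1.498603462769085,3.0,fibrotic
```

Area `A` grows without limit, strain `ε` collapses toward zero (the two are
reciprocal under the constant boundary force), activation `a` saturates near
its fibrotic maximum `w2 − c ≈ 1.499`, and agent density `D` reaches the
carrying capacity `Dmax = 3` — the myofibroblast-dominated end state. An
injury multiplier below 6.03 instead relaxes back to `(A, ε, a, D) =
(1, 1, 0, 0.3)`.

Full network experiments run through the same CLI
(`fibronet simulate|generate|phase|assay|render`) or the library API
(`fibronet.run_simulation`, `fibronet.replicate_study`,
`fibronet.ablation`).

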