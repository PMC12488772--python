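# ucbridge

Genomic prediction of cross usefulness and donor prioritisation for
*bridging populations* — intermediate populations used to improve
donor × elite progeny before genetic-resource alleles are introduced into
an elite breeding program.

Breeders who want to widen the genetic base of elite maize material face
two linked questions: *which donor × elite crosses are worth making*, and
*which new donors would complement the material already in use*?
`ucbridge` implements the quantitative-genetics machinery to answer both
from marker data and a modest multiparental experiment: simulation of
BC1S2 bridging designs, per-family mixed-model estimation, GBLUP and
Bayesian ridge regression genomic prediction, analytic progeny-variance
and usefulness-criterion prediction for untested crosses, and
haplotype-based donor ranking.

## The models in brief

**Family model.** For each BC1S2 family *k* with adjusted hybrid means
*Y*, a mixed model `Y = mu_k + A + E`, `A ~ N(0, K sigma2_Ak)` is fitted
by REML, where `K` is a NOIA (genotype-frequency-centred) kinship matrix
built on the family itself. The family's merit is summarised by the
usefulness criterion `UC_k = mu_k + i·h·sigma2_Ak` with selection
intensity `i = 2.07` (5% selected fraction) and accuracy `h = 1`.

**Cross prediction.** For an *untested* cross R × D, marker effects
`beta` are estimated by Bayesian ridge regression (Gibbs sampling,
scaled-inverse-chi-square priors, 20 000 iterations, 5 000 burn-in,
thinning 5 → S = 3000 samples). The progeny mean is the
backcross-weighted parental value `mu_hat = 3/4 x_R beta + 1/4 x_D beta`.
The progeny variance is the quadratic form `beta' Sigma beta`, where the
marker covariance among BC1S2 progeny is

```
Sigma_ij = D^p_ij (1 − 2 c_ij)(3 − 2 c_ij)
D^p      = (x_R − x_D)(x_R − x_D)' / 16
c_ij     = [2c¹/(1+2c¹)]·(1 − (1−2c¹)²/4) + ((1−2c¹)/2)²/2
c¹_ij    = (1 − e^(−2 d_ij))/2            (Haldane)
```

evaluated either with the posterior-mean effects (VPM) or averaged over
MCMC samples (PMV).

**Donor prioritisation.** Haplotypic estimated breeding values (HEBV)
are computed in sliding windows of 100 SNPs with a 20-SNP step; the H
criterion of a candidate donor is `lambda * sum_h max(HEBV)` over the
candidate, the recipient and its already-incorporated donors, with
`lambda = step/window = 0.2`. Donors are ordered by greedy forward
selection; a UC-based ranking is reported alongside for comparison.

A synthetic-data module generates complete studies with the expected
statistical structure (incomplete 7 × 9 crossing design, 20 connected
families of 38–66 BC1S2 individuals, Haldane meiosis, additive traits
driven by QTL that the marker panel tags but does not contain), so every
stage is testable without any private data.

## Worked example

Predict the mean, progeny variance and usefulness criterion of one cross
from a training set of half-sib families (RD composition — families
sharing the target's recipient or donor):

```python
import numpy as np
from ucbridge import simdata, experiment, brr, crosspred

study = simdata.simulate_study(seed=42, n_chromosomes=5,
                               chromosome_length=1.6,
                               markers_per_chromosome=60)
target = study.design.iloc[0]            # R1 x D9, 66 BC1S2 progeny

ts = experiment.build_training_set(study.design, study.families,
                                   target.family_id, "RD", vs_ids=[])
y = study.trait_values("trait1")
post = brr.fit_brr(y.loc[ts.member_ids].to_numpy(),
                   study.progeny.loc[ts.member_ids].to_numpy(dtype=float),
                   seed=1)
pred = crosspred.predict_cross(
    target.recipient_id, target.donor_id,
    study.parents.loc[target.recipient_id].to_numpy(),
    study.parents.loc[target.donor_id].to_numpy(),
    study.gmap, post)
```

Output for this seed:

```
RD training set: 214 individuals from families ['R1xD3', 'R6xD9', 'R1xD1', 'R4xD9']
retained MCMC samples: 3000
predicted cross mean        mu_hat      = 0.036
progeny variance (VPM)      sigma2_vpm  = 0.008
progeny variance (PMV)      sigma2_pmv  = 0.027
usefulness criterion (VPM)  uc_vpm      = 0.053
usefulness criterion (PMV)  uc_pmv      = 0.091
realized family mean (observed phenotypes) = 0.082
```

`mu_hat` is the predicted progeny mean on the trait scale (the realized
family mean of this simulated cross is 0.082, predicted here from
relatives only); `sigma2_vpm <= sigma2_pmv` always holds, since PMV adds
the posterior spread of the effects through the positive-semidefinite
`Sigma`; the UC values combine mean and variance into the expected merit
of the selected progeny fraction.

The same analysis is available from the shell:

```bash
ucbridge simulate --out data/ --seed 42
ucbridge fit-family --data data/ --trait trait1 --out m1.tsv
ucbridge run-all --out run/ --seed 1
```

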