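# pronyfit

Automated characterization of hyper-viscoelastic materials from
frequency-domain dynamic mechanical analysis (DMA) data, built for soft
biological tissues such as articular cartilage.

DMA measures a material's storage modulus E′(f) and loss modulus E″(f) over a
frequency sweep, but time-domain simulation (e.g. finite-element analysis)
needs a Prony-series relaxation function alongside a hyperelastic law.
`pronyfit` performs that conversion automatically: a two-stage optimization —
multi-start interior-point (log-barrier) seeding followed by a genetic
algorithm whose fitness includes forward time-domain simulation of ramp and
sinusoidal compression tests — identifies the normalized Prony spectrum that
best reproduces both the frequency-sweep moduli and the time-domain
validation curves, with a fixed Ogden hyperelastic model carrying the
instantaneous nonlinearity.

## The model

The viscoelastic response is a generalized Maxwell (Prony) series with
normalized relaxation modulus

    mu(t) = g_inf + sum_{k=1..N} g_k exp(-t / tau_k),        g_inf = 1 - sum g_k

whose frequency-domain forms are

    u'(w)  = g_inf + sum_k g_k (w tau_k)^2 / (1 + (w tau_k)^2)
    u''(w) =         sum_k g_k (w tau_k)   / (1 + (w tau_k)^2)

subject to 0 < g_k < 1, sum g_k <= 1 and tau_k <= tau_{k+1}.  The
instantaneous elasticity is an incompressible Ogden solid
U = sum_i (2 mu_i / alpha_i^2)(l1^a_i + l2^a_i + l3^a_i − 3); its uniaxial
Cauchy stress sigma0(lambda) is convolved with the Prony relaxation function
(quasi-linear viscoelasticity) and integrated with the standard exponential
recursive update under stress control.

Fitness is two-track: every candidate is screened by the mean squared
relative misfit of u′/u″ against the training split of the (f, E′, E″)
dataset; the best `NumInGen` candidates are forward-simulated through a 1 s
stress ramp to 1.225 MPa plus a 1 s, 1 Hz sinusoid between 0.7 and 1.7 MPa,
and scored as averaged percentage differences against frozen log/exponential
fits of the validation ramp and hysteresis-loop branches.

## Worked example

`examples/04_seed_and_evolve.py` generates a noiseless synthetic 168-tuple
frequency sweep from a known N=1 ground truth (g = 0.4, tau = 0.1 s), builds
the validation curves from the truth's own simulated response, and runs the
seeded genetic search:

```
gen  0: best equation error 1.201e-17, best mean model error 0.444 %
...
gen  5: best equation error 1.201e-17, best mean model error 0.444 %

recovered g   = 0.4000  (truth 0.4)
recovered tau = 0.1000 s (truth 0.1)
```

The equation error is the mean squared relative misfit of the dynamic moduli
(~1e-17 means the data curves are reproduced exactly); the residual 0.444 %
mean model error is the irreducible lack-of-fit of the two-parameter log/exp
validation forms, not a parameter error.  The other examples cover the DMA
waveform reduction (`01`), the Prony forms themselves (`02`), hysteresis
simulation (`03`) and the shell interface (`05`).

The same loop is available from the shell:

```sh
pronyfit synth ws --seed 0                 # write a synthetic demo workspace
pronyfit run ws --out run -N 3 --iterations 20 --seed 1
pronyfit inspect run/backup.jsonl          # error-vs-generation table
```

Each run directory stores the resolved configs, the dataset split, one
JSON-lines record per generation (population, fitness, RNG state) and the
best Prony series — enough to reproduce or resume (`--resume`) the run.

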