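# aprepair

**In-silico repair of mutant cardiac action potentials with optimal
combinations of existing drugs.**

Some ion-channel mutations reshape the cardiac action potential (AP) in
dangerous ways. The short QT syndrome type 1 (SQT1) mutation hERG N588K is
a gain of function of the rapid delayed-rectifier K⁺ current I_Kr: it
shifts the channel's inactivation to more positive voltages, the current
grows, the ventricular AP shortens, and the Ca²⁺ transient — and hence
contraction — is depressed. `aprepair` asks a pharmacological question of
this electrophysiological problem: *given a library of characterised
existing drugs, which combination of doses makes the mutant myocyte's AP
and Ca²⁺ transient look as wild-type as possible?*

The package is aimed at computational electrophysiologists and
systems-pharmacology researchers who want a compact, fully testable
implementation of the whole chain: cell model → drug model → biomarkers →
cost → dose optimisation.

## The model

**Currents.** Every membrane current is factorised as ρ·J: a dimensionless
channel-density scaling ρ (all that changes between hiPSC-CM, rabbit and
adult-human parameterisations) and a per-channel flux J = g₀·o·(v − E)
(all that the mutation and drugs act on). The N588K mutation enters only
through the I_Kr inactivation-gate steady state,

    x_Kr2,∞(v) = 1 / (1 + exp((v + 70) / 20.9))            (WT)
    x_Kr2,∞(v) = 1 / (1 + exp((v + 70 − 62) / (20.9·1.85)))  (N588K)

**Drugs.** A drug at concentration D (μM) scales a current by
1 + η(D) with the Hill form η(D) = (εD)^H / ((εD)^H + 1) · E, where
1/ε = EC₅₀, H is the Hill coefficient and E the maximum effect (E = −1:
full block; E > 0: agonist). Several drugs combine *multiplicatively*
per current — independent binding — giving the factor
F_i(D) = Π_k (1 + η_ik(D_k)). Because F scales J only, the same factors
are valid for every cell type.

**Cost.** A beat is summarised by 18 biomarkers (RMP, APA, dv/dt_max,
APD10…APD90, CaR, CaA, dc/dt_max, CaD30/50/80). The cost of a dose
vector is C(D) = Σ_j w_j |R_j^M(D) − R_j^W| / |R_j^W| with weights 1,
except 5 on APD80, APD90 and dv/dt_max.

**Search.** Doses are bounded (95%-saturation cap, or D ≤ min EC₅₀, or
D ≤ min EC₅₀/2) and optimised incrementally: the best n-drug solution
seeds every (n+1)-drug candidate with the new drug at dose zero, so the
optimal cost is non-increasing in n.

The shipped nine-drug library (I_Kr blockers quinidine, ivabradine,
ajmaline, mexiletine, disopyramide, propafenone, amiodarone and the
agonists BAY K 8644 on I_CaL and veratridine on I_NaL) carries literature
EC₅₀/H/E values per current. The cell model itself is a documented
*surrogate* ventricular parameter set (see `docs/methods.md`): it
reproduces the qualitative SQT1 phenotype, not any published cell line,
and any parameter set following the same schema can be dropped in.

## Worked example

Closed-form drug arithmetic (no simulation): the published optimal
two-drug doses, veratridine 1.86 μM + disopyramide 3.03 μM, act on the
mutant currents as

```sh
$ aprepair percent-change --dose veratridine 1.86 --dose disopyramide 3.03
I_Kr    -27.1%
I_CaL   -0.2%
I_Na    -0.4%
I_NaL   +171.0%
I_f     +0.0%
```

— a 27% block of the overactive mutant I_Kr plus a near-saturating
(95% of E) enhancement of the late Na⁺ current that props the plateau
back up.

End-to-end on the surrogate adult-human SQT1 model:

```sh
$ aprepair optimize --max-drugs 2
n=1  cost=1.886  [disopyramide 72.92 uM]
n=2  cost=0.268  [disopyramide 10.64 uM, veratridine 1.854 uM]
```

The best single drug (disopyramide, an I_Kr blocker) leaves a sevenfold
larger residual cost than the two-drug combination, in which veratridine
sits essentially at its saturation cap (1.857 μM) and a much lower
disopyramide dose supplies the complementary I_Kr block — no single
mechanism can both lengthen the plateau and renormalise its shape.
`aprepair repair` writes the full report set (traces, biomarker tables,
dose tables, machine-readable summary); `aprepair scan-pairs` produces
the 9×9 matrix of all two-drug optima.

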