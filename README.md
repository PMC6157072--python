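# matekit

Optimal contribution selection and mate allocation for breeding and
conservation programs.

Breeding programs that always use their best individuals gain quickly and
then stall: concentrating contributions in a few elite parents erodes the
genetic diversity that future gain is made of. Conservation programs face
the mirror problem — keeping contributions balanced enough that a small
population stays viable. `matekit` addresses both by optimizing a full
**mating plan**: which candidates become parents, how many matings each
contributes, who mates whom, and (optionally) which selected parents are
genome edited.

Given contribution proportions `x` and a coancestry (kinship) matrix `C`,
the package works with three objectives:

* genetic gain `x'a` (criterion `a` standardized over candidates),
* group coancestry `x'Cx` — the expected mean kinship of the next
  cohort, whose growth measures diversity loss,
* mean expected progeny inbreeding — the mean parental coancestry over
  the actual matings, which depends on mate allocation.

A run can maximize gain, minimize group coancestry, minimize mating
inbreeding, or maximize gain under a coancestry bound `C*` set as a
value, a rate, a percent of the achievable span, or trigonometric
degrees between the two objectives (0° = pure gain, 90° = pure
diversity). The search is a differential-evolution algorithm over a
ranking-based plan encoding with deterministic trim/round/swap repairs
and penalties for what cannot be repaired; multi-objective runs use the
two-step epsilon-constraint recipe (solve the single objectives to find
bounds, then sweep degree targets) to trace the Pareto frontier. An
editing budget adds per-candidate "edit rank" genes so that *which males
are selected* and *which are edited* are optimized jointly.

Coancestry can be supplied as a matrix, built from a pedigree (tabular
method, `theta = A/2`), or from biallelic markers (identity-by-state
allele sharing). See `docs/methods.md` for the model, conventions and
limitations.

## Worked example

Six candidates; `A`/`B` are full sibs (kinship 0.25) and `C`/`D` half
sibs (0.125); criteria range from 0.5 to 3.0. We want 3 matings, at most
2 per parent, no selfing, balanced at 45°:

```text
# cand.txt                 # spec.txt
A 0 2.0                    CandidateFile cand.txt
B 0 1.0                    CoancestryMatrixFile coa.txt
C 0 3.0                    NumberOfMatings 3
D 0 1.5                    MaxContributions 2
E 0 0.5                    AllowSelfing No
F 0 2.5                    Mode Target
                           TargetDegrees 45
                           EvolPopSize 24
                           EvolIterations 200
                           ConvergenceWindow 50
                           Seed 7
                           OutputBasename example
```

```sh
$ matekit run spec.txt
mode: target  seed: 7
gain 0.585540  coancestry 0.145833  inbreeding 0.000000  penalty 0.000000
```

The summary file records the objective-space bounds and the resolved
target: the max-gain solve reaches gain 0.878 at coancestry 0.1667, the
min-coancestry solve reaches 0.1042, so 45° resolves to
`C* = 0.1042 + cos(45°) * (0.1667 - 0.1042) = 0.1484`. The plan achieves
gain 0.586 (standardized units) at coancestry 0.1458 — inside the bound
with zero penalty — by shifting matings from the sib pair toward the
unrelated high-merit candidates:

```text
$ cat example_Contributors.txt
Id Gender Criterion nContributions xContribution Edited
A 0 2.000000 2 0.333333 No
C 0 3.000000 1 0.166667 No
D 0 1.500000 1 0.166667 No
F 0 2.500000 2 0.333333 No

$ cat example_MatingPlan.txt
Mating Parent1 Parent2 ExpectedInbreeding
1 C F 0.000000
2 F A 0.000000
3 A D 0.000000
```

Every mating pairs unrelated parents, so expected progeny inbreeding is
zero even though `C` and `D` are half sibs — that is the mate-allocation
half of the joint optimization. Re-running with the recorded seed
reproduces these files byte for byte. `Mode Frontier` instead writes a
`*_Frontier.txt` table (degrees, gain, coancestry, normalized values,
inbreeding) plus one plan per degree target, ready for any plotting tool.

The synthetic-data generator doubles as a demo:

```sh
matekit simulate --kind markers --n 32 --loci 200 --out syn
matekit demo --cycles 12 --degrees 35 --seed 1
```

`demo` runs a toy recurrent-selection program (16 crosses × 10 progeny
per cycle, true-merit selection) under truncation with one and four
crosses per parent and under a 35° balanced target, and reports each
scheme's genetic gain, genic-SD loss and conversion efficiency.

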