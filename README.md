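# rbcedit

Analyses around CRISPR–Cas9 multi-knockout engineering of an immortalised
human erythroblast line: can a single red-cell product lacking several
blood-group proteins service patients whom the donor system cannot match,
and is the edited clone's genome and proteome otherwise undisturbed?

The package implements three connected desk-scale analyses, plus the seeded
simulators that generate every input they need:

1. **Off-target attribution screen** (`rbcedit.screen`). Somatic SNVs and
   indels (≤ 50 nt) unique to the edited clone are found by exact-key
   differencing of normalized callsets against the parent line. Each
   mutation's wild-type neighbourhood (±100 bp) is scanned gaplessly on both
   strands against every guide, and a mutation is attributed to Cas9 when
   some alignment has a valid attribution PAM (NRG), a predicted blunt cut
   (3 bp 5′ of the PAM) proximal to the mutation, and either
   *m* < 6 protospacer mismatches or a perfectly conserved 10-bp
   PAM-proximal seed:

   ```
   attributed  ⇔  ∃ site:  PAM ∈ NRG
                        ∧  |cut(site) − anchor(variant)| ≤ τ      (τ = 5 bp)
                        ∧  ( m(site) ≤ 5  ∨  seed(site) intact )
   ```

2. **Antigen-knockout coverage** (`rbcedit.coverage`). A surveyed cohort of
   56 alloimmunised or rare-phenotype patients, each requiring a set of
   blood-group systems (MNS/GPB, Rh, Duffy, Kell, H, Lutheran, Kidd) absent
   from any transfused cell. A patient is served by a knockout panel *P*
   when their requirement set *R* satisfies *R ⊆ P* (McLeod-syndrome
   patients are never servable: XK is not a removable target). Includes
   greedy and exhaustive set-cover panel planning.

3. **Proteome ratio arithmetic** (`rbcedit.proteome`). TMT abundance ratios
   as replicate-mean quotients, the 1 % FDR / ≥ 2-peptide filter, integer
   percent reductions, and the fraction of membrane/cytoskeletal proteins
   with ≥ twofold reduction.

## Worked example

```sh
python analysis/01_simulate_inputs.py
python analysis/02_offtarget_screen.py
python analysis/03_antigen_coverage.py
python analysis/04_proteome_ratios.py
```

prints (abridged):

```
105 somatic variants unique to the edited clone: 5 on-target,
    0 off-target attributed, 100 unattributed background
no background variant met the attribution criteria (the expected null result)
54 of the 56 surveyed patients are served by the seven-system knockout
48 of 56 are served by the five-major-system knockout; adding LUTHERAN
    gains 3, adding KIDD gains 3
CD47: ratio 0.61 -> 39% reduction
ICAM4: ratio 0.07 -> 93% reduction
XK: ratio 0.63 -> 37% reduction
```

Reading: the five planted biallelic cut-site indels are recovered as
on-target edits and none of the 200 background SNVs is mistaken for Cas9
activity; knocking out all seven surveyed systems services every patient
except the two with McLeod syndrome; the five-system panel (GPB, Rh, Duffy,
Kell, H) services 48, and Lutheran/Kidd each add three more; the knockdown
of the Rh-complex partners CD47 and ICAM-4 and the Kell partner XK follows
directly from their printed abundance ratios.

The same stages are available as a CLI (`rbcedit simulate|screen|coverage|
proteome|run`); the numbered analysis scripts are the canonical drivers.

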