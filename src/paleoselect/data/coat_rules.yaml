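# Epistasis rule table for the eight-marker horse coat-colour panel.
#
# This file is the editable source of truth for the genotype -> phenotype map.
# The rules follow standard horse coat-colour genetics: homozygous MC1R "e/e"
# (chestnut) is epistatic over ASIP; homozygous ASIP "a/a" on a non-chestnut
# base gives black, otherwise bay; silver is expressed only on coats with
# black pigment (bay, black); pearl is expressed when homozygous or when a
# single pearl allele is combined with at least one cream allele; cream is
# incompletely dominant (one dose dilutes, two doses give a double dilute);
# tobiano, sabino and leopard are dominant spotting patterns.
#
# mode: dominant   -> expressed at derived dosage >= 1
#       recessive  -> expressed at derived dosage == 2
#       incomplete -> dose-dependent (dosage 1 and 2 are distinct states)
loci:
  - name: MC1R
    gene: MC1R
    wild_allele: E
    derived_allele: e
    role: base_extension
    mode: recessive
  - name: ASIP
    gene: ASIP
    wild_allele: A
    derived_allele: a
    role: base_agouti
    mode: recessive
  - name: PMEL17
    gene: PMEL17
    wild_allele: Z+
    derived_allele: Z
    role: dilution
    trait: silver
    mode: dominant
    visible_on_bases: [bay, black]
  - name: MATP_cream
    gene: MATP
    wild_allele: C
    derived_allele: Cr
    role: dilution
    trait: cream
    mode: incomplete
  - name: MATP_pearl
    gene: MATP
    wild_allele: C
    derived_allele: prl
    role: dilution
    trait: pearl
    mode: recessive
    visible_het_with_cream: true
  - name: TRPM1_LP
    gene: TRPM1
    wild_allele: lp
    derived_allele: LP
    role: spotting
    trait: leopard
    mode: dominant
  - name: KIT_tobiano
    gene: KIT
    wild_allele: km
    derived_allele: KM1
    role: spotting
    trait: tobiano
    mode: dominant
  - name: KIT_sabino
    gene: KIT
    wild_allele: sb
    derived_allele: SB1
    role: spotting
    trait: sabino
    mode: dominant
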