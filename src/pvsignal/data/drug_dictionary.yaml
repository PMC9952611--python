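# Penicillin-class study drugs with ATC classification and best-effort
# brand/generic synonym lists.  Matching is exact after normalization
# (lowercase, whitespace collapse, trailing dosage tokens stripped), so the
# lists are editable without code changes.  Synonym sets must stay disjoint
# across drugs.
piperacillin\tazobactam:
  atc_class: Combinations of penicillins, incl. beta-lactamase inhibitors (J01CR)
  synonyms:
    - piperacillin/tazobactam
    - piperacillin-tazobactam
    - piperacillin and tazobactam
    - piperacillin sodium/tazobactam sodium
    - zosyn
    - tazocin
amoxicillin\clavulanic acid:
  atc_class: Combinations of penicillins, incl. beta-lactamase inhibitors (J01CR)
  synonyms:
    - amoxicillin/clavulanic acid
    - amoxicillin-clavulanate
    - amoxicillin and clavulanate potassium
    - co-amoxiclav
    - augmentin
ampicillin\sulbactam:
  atc_class: Combinations of penicillins, incl. beta-lactamase inhibitors (J01CR)
  synonyms:
    - ampicillin/sulbactam
    - ampicillin-sulbactam
    - ampicillin and sulbactam
    - unasyn
ampicillin:
  atc_class: Penicillins with extended spectrum (J01CA)
  synonyms:
    - ampicillin sodium
    - ampicillin trihydrate
    - principen
amoxicillin:
  atc_class: Penicillins with extended spectrum (J01CA)
  synonyms:
    - amoxicillin trihydrate
    - amoxil
    - moxatag
piperacillin:
  atc_class: Penicillins with extended spectrum (J01CA)
  synonyms:
    - piperacillin sodium
    - pipracil
cloxacillin:
  atc_class: Beta-lactamase-resistant penicillins (J01CF)
  synonyms:
    - cloxacillin sodium
    - cloxapen
flucloxacillin:
  atc_class: Beta-lactamase-resistant penicillins (J01CF)
  synonyms:
    - flucloxacillin sodium
    - floxapen
nafcillin:
  atc_class: Beta-lactamase-resistant penicillins (J01CF)
  synonyms:
    - nafcillin sodium
    - nallpen
    - unipen
oxacillin:
  atc_class: Beta-lactamase-resistant penicillins (J01CF)
  synonyms:
    - oxacillin sodium
    - bactocill
penicillin G:
  atc_class: Beta-lactamase-sensitive penicillins (J01CE)
  synonyms:
    - benzylpenicillin
    - penicillin g potassium
    - penicillin g sodium
    - penicillin g benzathine
    - pfizerpen
    - bicillin l-a
penicillin V:
  atc_class: Beta-lactamase-sensitive penicillins (J01CE)
  synonyms:
    - phenoxymethylpenicillin
    - penicillin v potassium
    - penicillin vk
    - pen-vee k
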