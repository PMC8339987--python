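# Admissible-relation map over unordered entity-type pairs.
# Each pair of entity types admits at most one non-null relation; every pair
# not listed here admits only NoRelation.  The full published edge diagram is
# not enumerable from text alone, so this file is the reference reconstruction:
# it contains the minimal edges needed for every catalogue question to be
# answerable from (entity, relation, entity) triples.  Override with --schema.
schema_version: 1
edges:
  At:
    - [Location, Mass]
    - [Location, LymphNode]
    - [Location, Effusion]
    - [Location, PAOP]
  SizeOf:
    - [Size, Mass]
    - [Size, LymphNode]
  Negate:
    - [Negation, Mass]
    - [Negation, LymphNode]
    - [Negation, Bronchus]
    - [Negation, Pleura]
    - [Negation, Vessel]
    - [Negation, VertebralBody]
    - [Negation, Effusion]
    - [Negation, PAOP]
  Related:
    - [Mass, Density]
    - [Mass, Enhancement]
    - [Mass, Shape]
    - [Mass, Bronchus]
    - [Mass, Pleura]
    - [Mass, Vessel]
    - [Mass, VertebralBody]
    - [Mass, PAOP]
    - [Mass, Effusion]
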