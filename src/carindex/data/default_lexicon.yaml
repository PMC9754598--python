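# Default department-classification lexicon for the Carceral Resource Index.
#
# Patterns are matched case-insensitively as substrings of the
# whitespace-normalized department name, longest pattern first; ties are
# broken by order of appearance in this file.  Category order matters only
# for tie-breaking.  Departments matching no pattern fall into "other":
# they count toward the total budget but toward no numerator category.
carceral:
  - police
  - corrections
  - correction
  - prosecutor
  - prosecution
  - district attorney
  - public defender
  - public defense
  - court
  - sheriff
  - probation
  - community supervision
  - jail
  - detention
  - law enforcement
health:
  - health and human services
  - public health
  - health
  - human services
  - public spaces
  - public space
  - parks and recreation
  - parks
  - recreation
support:
  - housing
  - neighborhood development
  - neighborhood services
  - employment
  - workforce development
  - community engagement
  - arts and culture
  - cultural affairs
  - arts
excluded:
  - chief medical examiner
  - medical examiner
  - coroner
  - environmental protection
  - child and family services
  - children and family services
  - children's services
  - child protective
  - education
  - school
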