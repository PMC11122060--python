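# Catalog of the ten fundamental missingness scenarios in healthcare
# facilities, with coarse assumption flags for the theoretical inquiries:
#   mechanism_class   -- causal structure the scenario implies for R nodes
#   shift_prone       -- missingness distribution may shift at deployment
#   nde_risk          -- measurement may directly affect study variables
#   interference_risk -- availability of one sample may affect another
#   selection_bias    -- whole rows may be omitted invisibly
#   monotone_inducing -- the scenario alone tends to nest the patterns
#   sensitivity_hint  -- how to anchor a sensitivity parameter in the domain
scenarios:
- id: 1
  title: Patient complete non-visit
  agent: patient
  mechanism_class: outcome_dependent
  shift_prone: false
  nde_risk: false
  interference_risk: true
  selection_bias: true
  monotone_inducing: false
  sensitivity_hint: >-
    Odds of visiting a healthcare facility for healthy versus sick
    populations; anchor from epidemiologic studies and public health
    reports on care-seeking behaviour.
- id: 2
  title: Missing follow-up visit due to health status
  agent: patient
  mechanism_class: outcome_dependent
  shift_prone: false
  nde_risk: false
  interference_risk: true
  selection_bias: false
  monotone_inducing: false
  sensitivity_hint: >-
    Odds of returning for a follow-up visit given health trajectory;
    anchor from dropout rates in comparable longitudinal cohorts.
- id: 3
  title: Missing measurements due to health-related events during hospitalization
  agent: patient
  mechanism_class: outcome_dependent
  shift_prone: false
  nde_risk: false
  interference_risk: false
  selection_bias: false
  monotone_inducing: false
  sensitivity_hint: >-
    Frequency of interrupting events (code blue, ward transfer) per
    hospitalization stratum, from facility incident statistics.
- id: 4
  title: Missing measurements due to patient’s refusal
  agent: patient
  mechanism_class: self_masking_possible
  shift_prone: false
  nde_risk: false
  interference_risk: false
  selection_bias: false
  monotone_inducing: false
  sensitivity_hint: >-
    Refusal may depend on the unmeasured value itself (e.g. pain
    intolerance); elicit plausible refusal odds per severity stratum.
- id: 5
  title: Missing measurements due to diagnostic irrelevance
  agent: physician
  mechanism_class: observed_history
  shift_prone: true
  nde_risk: true
  interference_risk: false
  selection_bias: false
  monotone_inducing: true
  sensitivity_hint: >-
    Odds of making an observation for relatively healthy versus sick
    patients, inferred from guidelines, protocols and attending
    physicians.
- id: 6
  title: Missing measurements outside protocols requirements
  agent: facility
  mechanism_class: observed_history
  shift_prone: true
  nde_risk: true
  interference_risk: false
  selection_bias: false
  monotone_inducing: false
  sensitivity_hint: >-
    Protocol coverage rates per admission condition; protocol revisions
    shift the mechanism at deployment.
- id: 7
  title: Unavailability or shortage of resources
  agent: facility
  mechanism_class: exogenous
  shift_prone: true
  nde_risk: false
  interference_risk: true
  selection_bias: false
  monotone_inducing: false
  sensitivity_hint: >-
    Order-fulfilment rates under queueing or equipment downtime; cost
    reductions or upgrades shift test frequency at deployment.
- id: 8
  title: Unrecorded observations
  agent: facility
  mechanism_class: exogenous
  shift_prone: false
  nde_risk: false
  interference_risk: false
  selection_bias: false
  monotone_inducing: false
  sensitivity_hint: >-
    Recording-failure rates of the data-collection software or practice
    style; values were seen and acted upon but never stored.
- id: 9
  title: Omission of data samples based on inclusion/exclusion criteria
  agent: preprocessing
  mechanism_class: self_masking_possible
  shift_prone: false
  nde_risk: false
  interference_risk: false
  selection_bias: true
  monotone_inducing: false
  sensitivity_hint: >-
    The applied inclusion/exclusion rules themselves; value-range
    criteria can mask a variable as a function of its own value.
- id: 10
  title: Omission of invalid data entries
  agent: preprocessing
  mechanism_class: exogenous
  shift_prone: false
  nde_risk: false
  interference_risk: false
  selection_bias: false
  monotone_inducing: false
  sensitivity_hint: >-
    Error-entry rates (handwriting, corrupted pages, ERROR codes),
    typically unrelated to the underlying health values.
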