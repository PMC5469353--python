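# Trial-level constants for the packaged cohort.
screened: 37
n_sessions: 10
session_minutes: 90
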