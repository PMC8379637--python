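# SARS-CoV-2 surveillance scenario: Austria, 12-14 November 2020.
# Health-care workforce and general population, each split into the
# tested (high-prevalence) and untested (low-prevalence) strata.
name: austria_nov2020
budget_tests: 103621
max_stages: 2
max_group: 100
subpopulations:
  - name: healthcare_high_prevalence
    size: 1413
    prevalence: 0.196
    fp_cost: 6
    fn_cost: 33
  - name: healthcare_low_prevalence
    size: 120154
    prevalence: 0.029
    fp_cost: 6
    fn_cost: 33
  - name: general_high_prevalence
    size: 102208
    prevalence: 0.196
    fp_cost: 1
    fn_cost: 33
  - name: general_low_prevalence
    size: 8693070
    prevalence: 0.029
    fp_cost: 1
    fn_cost: 33
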