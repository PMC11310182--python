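# Sequentialization rules for the synthetic lung-cancer pathway.
# Source patterns name activities that co-occur in one parallel (same-day)
# group; "..." binds the unnamed remainder. Targets impose the clinically
# known execution order on the named activities only.
rules:
  - name: surgery-order
    source: "+( 'Excision of Lung and Bronchus', 'X-ray', 'Removal of Therapeutic Appliances', ... )"
    target: "+( ->( 'Excision of Lung and Bronchus', 'X-ray', 'Removal of Therapeutic Appliances' ), ... )"
  - name: ct-before-biopsy
    source: "+( 'CT scan', 'Biopsy', ... )"
    target: "+( ->( 'CT scan', 'Biopsy' ), ... )"
  - name: ct-before-bronchoscopy
    source: "+( 'CT scan', 'Bronchoscopy', ... )"
    target: "+( ->( 'CT scan', 'Bronchoscopy' ), ... )"
iteration_cap: 100
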