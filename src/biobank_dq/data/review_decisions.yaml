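- rule_id: CP-basic_info-residence_code
  action: set_severity
  new_severity: W
- rule_id: CP-basic_info-disease_group
  action: set_severity
  new_severity: W
- rule_id: CP-basic_info-diagnosis_date
  action: set_severity
  new_severity: W
- rule_id: CP-basic_info-marital_status
  action: set_severity
  new_severity: W
- rule_id: CP-basic_info-education_level
  action: set_severity
  new_severity: W
- rule_id: CP-basic_info-insurance_type
  action: set_severity
  new_severity: W
- rule_id: CP-basic_info-specimen_note
  action: set_severity
  new_severity: W
- rule_id: CP-measurements-KBN_Donor
  action: set_severity
  new_severity: W
- rule_id: CP-measurements-height
  action: set_severity
  new_severity: W
- rule_id: CP-measurements-weight
  action: set_severity
  new_severity: W
- rule_id: CP-measurements-sbp
  action: set_severity
  new_severity: W
- rule_id: CP-measurements-dbp
  action: set_severity
  new_severity: W
- rule_id: CP-measurements-waist
  action: set_severity
  new_severity: W
- rule_id: CP-measurements-measure_date
  action: set_severity
  new_severity: W
- rule_id: CP-disease_history-KBN_Donor
  action: set_severity
  new_severity: W
- rule_id: CP-disease_history-DHDm
  action: set_severity
  new_severity: W
- rule_id: CP-disease_history-DHHtn
  action: set_severity
  new_severity: W
- rule_id: CP-disease_history-DHHep
  action: set_severity
  new_severity: W
- rule_id: CP-disease_history-DHTb
  action: set_severity
  new_severity: W
- rule_id: CP-disease_history-DHCvd
  action: set_severity
  new_severity: W
- rule_id: CP-disease_history-DHResp
  action: set_severity
  new_severity: W
- rule_id: CP-disease_history-DHRen
  action: set_severity
  new_severity: W
- rule_id: CP-disease_history-DHThy
  action: set_severity
  new_severity: W
- rule_id: CP-disease_history-DHAl
  action: set_severity
  new_severity: W
- rule_id: CP-disease_history-DHCa1
  action: drop
- rule_id: CP-disease_history-DHCa2
  action: drop
- rule_id: CP-disease_history-DHDm1
  action: drop
- rule_id: CP-disease_history-DHHtn1
  action: drop
- rule_id: CP-disease_history-DHHep1
  action: drop
- rule_id: CP-disease_history-DHTb1
  action: drop
- rule_id: CP-disease_history-DHCvd1
  action: drop
- rule_id: CP-disease_history-DHResp1
  action: drop
- rule_id: CP-disease_history-DHRen1
  action: drop
- rule_id: CP-disease_history-DHThy1
  action: drop
- rule_id: CP-disease_history-DHAl1
  action: drop
- rule_id: CP-disease_history-DHCa_other
  action: drop
- rule_id: CP-lab-KBN_Donor
  action: set_severity
  new_severity: W
- rule_id: CP-lab-total_protein
  action: set_severity
  new_severity: W
- rule_id: CP-lab-glucose
  action: set_severity
  new_severity: W
- rule_id: CP-lifestyle-KBN_Donor
  action: set_severity
  new_severity: W
- rule_id: CP-lifestyle-SM_A
  action: set_severity
  new_severity: W
- rule_id: CP-lifestyle-lifestyle_note
  action: drop
- rule_id: VR-measurements-dbp
  action: drop
- rule_id: VR-X-sbp_gt_dbp
  action: drop
- rule_id: VF-basic_info-marital_status
  action: set_severity
  new_severity: W
- rule_id: VF-basic_info-education_level
  action: set_severity
  new_severity: W
- rule_id: VF-measurements-waist
  action: set_severity
  new_severity: W
- rule_id: VF-lab-total_protein
  action: set_severity
  new_severity: W
- rule_id: VF-lab-glucose
  action: set_severity
  new_severity: W
- rule_id: AB-FWD-DHAl
  action: drop
- rule_id: AB-REV-DHHtn
  action: drop
- rule_id: AB-REV-DHHep
  action: drop
- rule_id: AB-REV-DHTb
  action: drop
- rule_id: AB-REV-DHCvd
  action: drop
- rule_id: AB-REV-DHResp
  action: drop
- rule_id: AB-REV-DHRen
  action: drop
- rule_id: AB-REV-DHThy
  action: drop
- rule_id: AB-REV-DHAl
  action: drop
- rule_id: UQ-basic_info-KBN_Donor
  action: set_severity
  new_severity: E
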