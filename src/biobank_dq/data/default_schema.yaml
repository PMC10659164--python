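# Default relational schema for a multicenter biobank clinical-epidemiological
# dataset (Korea Biobank Network style).  Raw values are strings; empty cell =
# null.  Coded fields enumerate their code sets; numeric fields carry plausible
# ranges in the stated unit.  Sentinel code 9 means "not investigated", and for
# disease-history detail fields code 0 means "not applicable / no disease".
tables:
  - name: basic_info
    key_fields: [KBN_Donor]
    fields:
      - {name: KBN_Donor, value_class: code-string, nullable: false}
      - {name: sex, value_class: coded-integer, nullable: false,
         allowed_codes: ["1", "2"]}
      - {name: birthdate, value_class: date-YYYYMMDD, nullable: false}
      - {name: receipt_date, value_class: date-YYYYMMDD, nullable: false}
      - {name: residence_code, value_class: coded-integer,
         allowed_codes: ["1", "2", "3", "4", "5", "6", "7", "8", "9", "10",
                         "11", "12", "13", "14", "15", "16", "17"]}
      - {name: disease_group, value_class: coded-integer,
         allowed_codes: ["1", "2", "3", "4", "5", "6", "7", "8", "9", "10",
                         "11", "12", "13", "14", "15", "16", "17", "18", "19",
                         "20", "21", "22", "23", "24", "25", "26"]}
      - {name: diagnosis_code, value_class: code-string, nullable: false,
         allowed_codes: ["C16.0", "C18.9", "C21.4", "C22.0", "C34.9", "C50.9",
                         "C61", "C73.9", "N80.0", "E11.9", "I10", "K29.7",
                         "J45.9", "B18.2", "D25.9"]}
      - {name: diagnosis_date, value_class: date-YYYYMMDD}
      - {name: marital_status, value_class: coded-integer,
         allowed_codes: ["1", "2", "3", "4", "9"]}
      - {name: education_level, value_class: coded-integer,
         allowed_codes: ["1", "2", "3", "4", "5", "9"]}
      - {name: insurance_type, value_class: coded-integer,
         allowed_codes: ["1", "2", "3", "9"]}
      - {name: occupation_text, value_class: free-text}
      - {name: family_history_text, value_class: free-text}
      - {name: specimen_note, value_class: free-text}

  - name: measurements
    key_fields: [KBN_Donor]
    fields:
      - {name: KBN_Donor, value_class: code-string, nullable: false}
      - {name: height, value_class: numeric, unit: cm, plausible_range: [50, 250]}
      - {name: weight, value_class: numeric, unit: kg, plausible_range: [0.1, 300]}
      - {name: sbp, value_class: numeric, unit: mmHg, plausible_range: [40, 300]}
      - {name: dbp, value_class: numeric, unit: mmHg, plausible_range: [20, 200]}
      - {name: waist, value_class: numeric, unit: cm, plausible_range: [30, 200]}
      - {name: measure_date, value_class: date-YYYYMMDD}
      - {name: measure_note, value_class: free-text}

  - name: disease_history
    key_fields: [KBN_Donor]
    fields:
      - {name: KBN_Donor, value_class: code-string, nullable: false}
      - {name: DHCa, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: DHDm, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: DHHtn, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: DHHep, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: DHTb, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: DHCvd, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: DHResp, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: DHRen, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: DHThy, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: DHAl, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: DHCa1, value_class: code-string,
         allowed_codes: ["0", "9", "C16", "C18", "C21", "C22", "C34", "C50",
                         "C61", "C73", "C97"]}
      - {name: DHCa2, value_class: code-string,
         allowed_codes: ["0", "9", "C16", "C18", "C21", "C22", "C34", "C50",
                         "C61", "C73", "C97"]}
      - {name: DHDm1, value_class: coded-integer, allowed_codes: ["0", "1", "2", "3", "9"]}
      - {name: DHHtn1, value_class: coded-integer, allowed_codes: ["0", "1", "2", "3", "9"]}
      - {name: DHHep1, value_class: coded-integer, allowed_codes: ["0", "1", "2", "3", "9"]}
      - {name: DHTb1, value_class: coded-integer, allowed_codes: ["0", "1", "2", "3", "9"]}
      - {name: DHCvd1, value_class: coded-integer, allowed_codes: ["0", "1", "2", "3", "9"]}
      - {name: DHResp1, value_class: coded-integer, allowed_codes: ["0", "1", "2", "3", "9"]}
      - {name: DHRen1, value_class: coded-integer, allowed_codes: ["0", "1", "2", "3", "9"]}
      - {name: DHThy1, value_class: coded-integer, allowed_codes: ["0", "1", "2", "3", "9"]}
      - {name: DHAl1, value_class: coded-integer, allowed_codes: ["0", "1", "2", "3", "9"]}
      - {name: DHCa_other, value_class: free-text}

  - name: lab
    key_fields: [KBN_Donor]
    fields:
      - {name: KBN_Donor, value_class: code-string, nullable: false}
      - {name: total_protein, value_class: numeric, unit: g/dL, plausible_range: [3, 12]}
      - {name: glucose, value_class: numeric, unit: mg/dL, plausible_range: [40, 500]}
      - {name: lab_note, value_class: free-text}

  - name: lifestyle
    key_fields: [KBN_Donor]
    fields:
      - {name: KBN_Donor, value_class: code-string, nullable: false}
      - {name: DR_A, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: DR_B, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: SM_A, value_class: coded-integer, allowed_codes: ["0", "1", "9"]}
      - {name: lifestyle_note, value_class: free-text}
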