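statement_code,impact_factor,statement_text
ICSR_RECEIVE_DATE_INACCURATE,ICSR_PROCESS,ICSR receive dates were inaccurately determined and/or recorded
ICSR_FOLLOWUP_NOT_PERFORMED,ICSR_PROCESS,"Follow-up on ICSRs was not performed, untimely and/or not documented"
AE_COLLECTION_PROCEDURE_INADEQUATE,ICSR_PROCESS,"Processes and/or procedures for case identification and collection of potential AEs were not defined, inadequate and/or not followed"
RECONCILIATION_NOT_PERFORMED,ICSR_PROCESS,"Reconciliation/case transmission verification with all relevant internal functions was not performed, untimely, inadequate and/or not documented"
RMP_COMMUNICATION_NOT_COMPLETED,RISK_MINIMIZATION,"Communication and/or submission of Risk Management Plans (RMPs) or additional RMinAs to the regulatory authority was not completed, untimely and/or not documented"
RMINA_LOCAL_OVERSIGHT_LACKING,RISK_MINIMIZATION,There was a lack of oversight for local implementation of PV activities or RMinAs
RSI_UPDATE_PROCEDURE_INADEQUATE,LOCAL_LABELS,"Procedures and/or processes for updating reference safety information were not defined, inadequate and/or not followed"
PROMO_MATERIAL_NOT_UPDATED,LOCAL_LABELS,Promotional material was not updated with new safety information or not updated in a timely manner
DHPC_DISTRIBUTION_UNTIMELY,DHPC,DHPC distribution to healthcare professionals was not performed in a timely manner
DHPC_RECIPIENT_LIST_INCOMPLETE,DHPC,The DHPC recipient list was incomplete or not maintained
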