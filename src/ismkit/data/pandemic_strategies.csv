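id,label,description
S1,Smart lockdown,Full lockdown enforced only in localities with a high risk index.
S2,Travel limitations,Restricting non-essential travel to slow transmission.
S3,Promoting online purchase behaviors,Encouraging consumers to buy through the internet instead of in person.
S4,Social distancing,Reducing physical interaction between people to lower transmission.
S5,Online education,Shifting teaching and learning to digital platforms.
S6,Prioritize key employees,Reducing on-site staff to essential workers to limit workforce exposure.
S7,Unemployment benefits from government,Incentive schemes for people who lost jobs during the pandemic.
S8,"Testing, tracing, and isolation",Early diagnosis of infected people with contact tracing and isolation.
S9,Strong leadership and government control,Committed government agenda and coordinated crisis response.
S10,Awareness on social media,Public campaigns about containment policies and healthy behavior.
S11,Work from home,Remote working to eliminate workplace contact.
S12,Explore new market opportunities,Pivoting businesses to pandemic-era products and services.
S13,Sealing the border,Closing national borders to prevent disease importation.
S14,Generating demand for domestic consumption,Meeting demand with domestic production while borders are closed.
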