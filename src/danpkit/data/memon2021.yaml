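# Mental-health factor model of work from home: three dimensions, 18 criteria.
# File order is semantic — it fixes the row/column order of every matrix in the
# pipeline.
name: work-from-home mental health factor model
dimensions:
  - code: C1
    label: Work-related stressors
    criteria:
      - code: C11
        label: Workloads
      - code: C12
        label: Work schedules
      - code: C13
        label: Structural emptiness
      - code: C14
        label: Unscheduled virtual meetings
      - code: C15
        label: Weekend tasks
      - code: C16
        label: High work expectations
      - code: C17
        label: Job insecurity
  - code: C2
    label: Non-work stressors
    criteria:
      - code: C21
        label: Distraction
      - code: C22
        label: Work-life imbalances
      - code: C23
        label: Time management issues
      - code: C24
        label: Domestic issues (or children's presence at home)
      - code: C25
        label: Laziness due to being at home
      - code: C26
        label: An inconsistent sleep schedule
  - code: C3
    label: Communication issues
    criteria:
      - code: C31
        label: Lack of social interaction
      - code: C32
        label: Improper guidelines
      - code: C33
        label: No feedback exchange
      - code: C34
        label: No proper collaboration with superiors and peers
      - code: C35
        label: A lack of coordination
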